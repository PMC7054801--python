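import numpy as np
import pandas as pd
import pytest

from claimscreen.synthetic_data import SimulationConfig, generate_population


def make_claims(rows):
    """Build a claims frame from (bene, date, code, system[, specialty]) tuples."""
    recs = []
    for row in rows:
        bene, date, code, system = row[:4]
        spec = row[4] if len(row) > 4 else np.nan
        recs.append(
            {
                "beneficiary_id": bene,
                "service_date": pd.Timestamp(date),
                "code": code,
                "code_system": system,
                "claim_source": "carrier",
                "provider_specialty": spec,
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "beneficiary_id", "service_date", "code", "code_system",
            "claim_source", "provider_specialty",
        ],
    )


@pytest.fixture(scope="session")
def small_population():
    """A 4,000-person synthetic population shared across read-only tests."""
    return generate_population(SimulationConfig(n_beneficiaries=4000, seed=17))
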