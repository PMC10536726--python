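import numpy as np
import pytest

from claimwatch.claims_data import Claim, ClaimsCorpus
from claimwatch.synthetic_claims import SyntheticWorldSpec, generate_corpus, generate_world

#: One claim for a 35-year-old woman with a broken ankle: ankle X-ray, X-ray
#: review, cast, and crutches under two diagnoses (S99 injury, M84 fracture).
BROKEN_ANKLE_ROWS = [
    ("1", "S99.919A", "73600", 35, "F"),
    ("1", "S99.919A", "73615", 35, "F"),
    ("1", "M84.371A", "L2108", 35, "F"),
    ("1", "M84.371A", "E0112", 35, "F"),
]

CLAIMS_HEADER = "claim_id,icd_code,cpt_code,age,gender"


def rows_to_csv(rows, path):
    lines = [CLAIMS_HEADER] + [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def broken_ankle_file(tmp_path):
    return rows_to_csv(BROKEN_ANKLE_ROWS, tmp_path / "claims.csv")


@pytest.fixture(scope="session")
def small_world():
    """Desk-scale world: 12 diagnoses, 80 procedures, 6 reserved."""
    spec = SyntheticWorldSpec(
        n_icd_categories=12,
        n_cpt_codes=80,
        n_reserved_oos_cpts=6,
        cpts_per_icd=(5, 9),
        seed=42,
    )
    return generate_world(spec)


@pytest.fixture(scope="session")
def small_corpus(small_world):
    return generate_corpus(small_world, n_claims=600, seed=7, id_prefix="TR")


def make_claim(claim_id="C1", icds=("A00",), cpts=("10000",), age=35, gender="female"):
    return Claim(
        claim_id=claim_id,
        icd_categories=tuple(icds),
        cpt_codes=tuple(cpts),
        age_years=age,
        gender=gender,
    )


def make_corpus(claims):
    return ClaimsCorpus(claims=list(claims))


def random_binary_batch(rng, n, m, p_one=0.3):
    return (rng.random((n, m)) < p_one).astype(float)


def random_prob_batch(rng, n, m):
    return rng.uniform(0.02, 0.98, size=(n, m))
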