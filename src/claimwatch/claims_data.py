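"""Domain model for outpatient claims and the delimited claims-table format.

An outpatient *claim* is one patient encounter: a set of claim lines sharing a
claim identifier, where each line carries exactly one CPT/HCPCS procedure code
together with an ICD-10 diagnosis code, the patient's age and gender.  Claims
routinely contain several procedure lines under one to three diagnoses.

Only the general ICD-10 diagnosis category (the first three characters) is
modelled; the trailing detail characters are discarded at ingest to reduce
feature sparsity downstream.  Age is bucketed into five clinically conventional
bands: under 18, 18-38, 39-59, 60-80, and 81 and older.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GENDERS: tuple[str, ...] = ("male", "female", "other")

_GENDER_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "o": "other",
    "other": "other",
    "u": "other",
    "unknown": "other",
}

#: Left edges of the five age buckets; each bucket is closed on the left and
#: open on the right, so bucket 1 is [18, 39) == ages 18 through 38 inclusive.
AGE_BUCKET_EDGES: tuple[int, ...] = (0, 18, 39, 60, 81)
AGE_BUCKET_LABELS: tuple[str, ...] = ("<18", "18-38", "39-59", "60-80", "81+")

REQUIRED_COLUMNS = ("claim_id", "icd_code", "cpt_code", "age", "gender")

MAX_ICD_CATEGORIES_PER_CLAIM = 3


class ClaimsFormatError(ValueError):
    """The claims table does not conform to the expected layout."""


class ClaimValidationError(ValueError):
    """A claim or claim line violates a domain invariant."""


def truncate_icd_category(icd_code: str) -> str:
    """Reduce a full ICD-10 code to its three-character general category.

    ``"S99.919A" -> "S99"``.  Codes are uppercased so that ingest is
    case-insensitive; the master vocabulary is uppercase.  Idempotent.
    """
    code = str(icd_code).strip()
    if len(code) < 3:
        raise ClaimValidationError(
            f"ICD-10 code {code!r} is shorter than the 3-character general category"
        )
    return code[:3].upper()


def bucket_age(age_years: int) -> int:
    """Map an age in years onto one of the five age buckets (0..4).

    Buckets are [0,18), [18,39), [39,60), [60,81), [81,inf) — i.e. under 18,
    18-38, 39-59, 60-80, 81 and older.
    """
    age = int(age_years)
    if age < 0:
        raise ClaimValidationError(f"age must be non-negative, got {age}")
    bucket = 0
    for i, edge in enumerate(AGE_BUCKET_EDGES):
        if age >= edge:
            bucket = i
    return bucket


def normalize_gender(value: str) -> str:
    key = str(value).strip().lower()
    try:
        return _GENDER_ALIASES[key]
    except KeyError:
        raise ClaimValidationError(
            f"unrecognized gender {value!r}; expected one of {sorted(set(_GENDER_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class ClaimLine:
    """One row of the claims table: a single procedure billed on a claim."""

    claim_id: str
    icd_code: str
    cpt_code: str
    age_years: int
    gender: str

    def __post_init__(self) -> None:
        if not str(self.cpt_code).strip():
            raise ClaimValidationError(f"claim {self.claim_id}: empty CPT code")
        if len(str(self.icd_code).strip()) < 3:
            raise ClaimValidationError(
                f"claim {self.claim_id}: ICD code {self.icd_code!r} too short"
            )
        if int(self.age_years) < 0:
            raise ClaimValidationError(f"claim {self.claim_id}: negative age")
        object.__setattr__(self, "cpt_code", str(self.cpt_code).strip().upper())
        object.__setattr__(self, "icd_code", str(self.icd_code).strip().upper())
        object.__setattr__(self, "gender", normalize_gender(self.gender))
        object.__setattr__(self, "claim_id", str(self.claim_id))
        object.__setattr__(self, "age_years", int(self.age_years))


@dataclass(frozen=True)
class Claim:
    """One patient encounter: grouped claim lines sharing a claim identifier.

    ``icd_categories`` holds the distinct 3-character general diagnosis
    categories (one primary plus up to two additional).  ``cpt_codes`` is the
    multiset of procedure codes across the claim's lines, in line order;
    repeated units of one procedure are preserved here and collapse to a single
    active bit only at encoding time.
    """

    claim_id: str
    icd_categories: tuple[str, ...]
    cpt_codes: tuple[str, ...]
    age_years: int
    gender: str

    def __post_init__(self) -> None:
        cats = tuple(sorted(set(self.icd_categories)))
        if not 1 <= len(cats) <= MAX_ICD_CATEGORIES_PER_CLAIM:
            raise ClaimValidationError(
                f"claim {self.claim_id}: expected 1-{MAX_ICD_CATEGORIES_PER_CLAIM} "
                f"ICD categories, got {len(cats)}"
            )
        if len(self.cpt_codes) < 1:
            raise ClaimValidationError(f"claim {self.claim_id}: no CPT codes")
        if int(self.age_years) < 0:
            raise ClaimValidationError(f"claim {self.claim_id}: negative age")
        object.__setattr__(self, "icd_categories", cats)
        object.__setattr__(self, "cpt_codes", tuple(self.cpt_codes))
        object.__setattr__(self, "gender", normalize_gender(self.gender))
        object.__setattr__(self, "age_years", int(self.age_years))

    @property
    def age_bucket(self) -> int:
        return bucket_age(self.age_years)

    def with_extra_cpts(self, codes: Sequence[str]) -> "Claim":
        """Return a copy of this claim with additional procedure codes appended."""
        return Claim(
            claim_id=self.claim_id,
            icd_categories=self.icd_categories,
            cpt_codes=self.cpt_codes + tuple(codes),
            age_years=self.age_years,
            gender=self.gender,
        )


@dataclass
class ClaimsCorpus:
    """An ordered collection of claims with unique claim identifiers."""

    claims: list[Claim] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.claim_id for c in self.claims]
        if len(set(ids)) != len(ids):
            seen, dupes = set(), set()
            for i in ids:
                (dupes if i in seen else seen).add(i)
            raise ClaimValidationError(f"duplicate claim_ids in corpus: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.claims)

    def __iter__(self) -> Iterator[Claim]:
        return iter(self.claims)

    def __getitem__(self, i: int) -> Claim:
        return self.claims[i]

    @property
    def claim_ids(self) -> list[str]:
        return [c.claim_id for c in self.claims]


def claims_from_lines(lines: Iterable[ClaimLine]) -> list[Claim]:
    """Group claim lines by claim_id into claims, in order of first appearance.

    Lines grouped under one claim must agree on age and gender (one patient per
    claim); a conflict raises :class:`ClaimValidationError` naming the claim.
    """
    order: list[str] = []
    grouped: dict[str, list[ClaimLine]] = {}
    for line in lines:
        if line.claim_id not in grouped:
            grouped[line.claim_id] = []
            order.append(line.claim_id)
        grouped[line.claim_id].append(line)

    claims = []
    for cid in order:
        group = grouped[cid]
        ages = {ln.age_years for ln in group}
        genders = {ln.gender for ln in group}
        if len(ages) > 1 or len(genders) > 1:
            raise ClaimValidationError(
                f"conflicting age/gender within claim_id {cid!r}: "
                f"ages={sorted(ages)}, genders={sorted(genders)}"
            )
        claims.append(
            Claim(
                claim_id=cid,
                icd_categories=tuple(truncate_icd_category(ln.icd_code) for ln in group),
                cpt_codes=tuple(ln.cpt_code for ln in group),
                age_years=group[0].age_years,
                gender=group[0].gender,
            )
        )
    return claims


def load_claims(path: str | Path, delimiter: str = ",", provenance: str = "") -> ClaimsCorpus:
    """Read a delimited claims table (one claim line per row) into a corpus.

    The table must have a header row with columns ``claim_id, icd_code,
    cpt_code, age, gender``.  Rows with equal ``claim_id`` are grouped into one
    claim; ICD codes are truncated to their general category; claim order
    follows first appearance in the file.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(
            f"claims table {path} is missing required column(s): {', '.join(missing)}"
        )
    lines = [
        ClaimLine(
            claim_id=row.claim_id,
            icd_code=row.icd_code,
            cpt_code=row.cpt_code,
            age_years=int(row.age),
            gender=row.gender,
        )
        for row in df.itertuples(index=False)
    ]
    return ClaimsCorpus(claims=claims_from_lines(lines), provenance=provenance or str(path))


def write_claims(corpus: ClaimsCorpus, path: str | Path, delimiter: str = ",") -> None:
    """Write a corpus back to the delimited one-line-per-procedure format.

    Each claim is expanded to one row per CPT code, cycling diagnosis
    categories across rows.  A claim with fewer procedures than diagnoses gets
    extra rows repeating its last procedure so every category is represented:
    the round trip preserves each claim's identifier, diagnosis-category set,
    procedure-code set, age and gender (unit counts only when the claim has at
    least as many procedures as diagnoses).
    """
    rows = []
    for claim in corpus:
        cats = claim.icd_categories
        cpts = claim.cpt_codes
        for i in range(max(len(cpts), len(cats))):
            rows.append(
                {
                    "claim_id": claim.claim_id,
                    "icd_code": cats[i % len(cats)],
                    "cpt_code": cpts[min(i, len(cpts) - 1)],
                    "age": claim.age_years,
                    "gender": claim.gender,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep=delimiter, index=False)
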