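"""Master code vocabulary and fixed-length binary encoding of claims.

Claims are encoded as fixed-length binary vectors laid out as four blocks:

    [ CPT multi-hot | ICD-category multi-hot | age one-hot (5) | gender one-hot (3) ]

The vocabulary is built once from a master corpus and then frozen, so that
training-time and scoring-time encodings are bit-identical and all vectors
share one length M.  CPT codes occurring in fewer than ``min_claims`` distinct
claims are dropped from the vocabulary so that models cannot flag procedures
as anomalous purely because they are rare.  Codes may additionally be declared
*reserved*: they own a dimension in the vocabulary but are exempt from the
rarity filter, which is what allows held-out test sets to contain procedure
codes whose dimensions were all-zero during training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .claims_data import GENDERS, Claim, ClaimsCorpus, bucket_age

logger = logging.getLogger(__name__)

N_AGE_BUCKETS = 5


class EncodingConfigError(ValueError):
    """Vocabulary or encoder configuration is unusable."""


@dataclass(frozen=True)
class CodeVocabulary:
    """Ordered master code lists defining the feature-vector layout.

    Both code lists are sorted lexicographically so dimension assignment is a
    deterministic function of the corpus contents, independent of claim order.
    """

    cpt_codes: tuple[str, ...]
    icd_categories: tuple[str, ...]
    cpt_claim_counts: dict[str, int] = field(default_factory=dict)
    reserved_cpts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name, codes in (("cpt_codes", self.cpt_codes), ("icd_categories", self.icd_categories)):
            if list(codes) != sorted(set(codes)):
                raise EncodingConfigError(f"{name} must be sorted and duplicate-free")


@dataclass(frozen=True)
class EncoderSpec:
    """Frozen encoding contract shared by training and scoring."""

    vocabulary: CodeVocabulary
    min_claims: int = 100
    n_age_buckets: int = N_AGE_BUCKETS
    gender_levels: tuple[str, ...] = GENDERS

    @property
    def n_cpt(self) -> int:
        return len(self.vocabulary.cpt_codes)

    @property
    def n_icd(self) -> int:
        return len(self.vocabulary.icd_categories)

    @property
    def feature_length(self) -> int:
        """Total vector length M = |CPT| + |ICD| + 5 + 3."""
        return self.n_cpt + self.n_icd + self.n_age_buckets + len(self.gender_levels)

    @property
    def cpt_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.vocabulary.cpt_codes)}

    @property
    def icd_index(self) -> dict[str, int]:
        return {c: self.n_cpt + i for i, c in enumerate(self.vocabulary.icd_categories)}

    @property
    def age_offset(self) -> int:
        return self.n_cpt + self.n_icd

    @property
    def gender_offset(self) -> int:
        return self.age_offset + self.n_age_buckets

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "cpt_codes": list(self.vocabulary.cpt_codes),
            "icd_categories": list(self.vocabulary.icd_categories),
            "cpt_claim_counts": dict(self.vocabulary.cpt_claim_counts),
            "reserved_cpts": sorted(self.vocabulary.reserved_cpts),
            "min_claims": self.min_claims,
            "n_age_buckets": self.n_age_buckets,
            "gender_levels": list(self.gender_levels),
            "block_order": ["cpt", "icd", "age", "gender"],
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EncoderSpec":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        vocab = CodeVocabulary(
            cpt_codes=tuple(doc["cpt_codes"]),
            icd_categories=tuple(doc["icd_categories"]),
            cpt_claim_counts={k: int(v) for k, v in doc["cpt_claim_counts"].items()},
            reserved_cpts=frozenset(doc["reserved_cpts"]),
        )
        return cls(
            vocabulary=vocab,
            min_claims=int(doc["min_claims"]),
            n_age_buckets=int(doc["n_age_buckets"]),
            gender_levels=tuple(doc["gender_levels"]),
        )


@dataclass(frozen=True)
class EncodedClaim:
    """A claim as a binary feature vector plus index maps back to codes."""

    claim_id: str
    vector: np.ndarray
    cpt_positions: tuple[int, ...]

    def active_cpt_codes(self, spec: EncoderSpec) -> tuple[str, ...]:
        return tuple(spec.vocabulary.cpt_codes[p] for p in self.cpt_positions)


@dataclass
class EncodedCorpus:
    """Ordered encoded claims plus the claims skipped as unencodable."""

    claims: list[EncodedClaim]
    skipped_claim_ids: list[str]
    spec: EncoderSpec

    def __len__(self) -> int:
        return len(self.claims)

    def matrix(self) -> np.ndarray:
        """Stack vectors into an (n_claims, M) float array."""
        if not self.claims:
            return np.zeros((0, self.spec.feature_length))
        return np.stack([c.vector for c in self.claims]).astype(np.float64)


def count_cpt_claims(corpus: ClaimsCorpus) -> dict[str, int]:
    """Number of distinct claims each CPT code appears in (not claim lines)."""
    counts: dict[str, int] = {}
    for claim in corpus:
        for code in set(claim.cpt_codes):
            counts[code] = counts.get(code, 0) + 1
    return counts


def build_encoder_spec(
    master_corpus: ClaimsCorpus,
    min_claims: int = 100,
    reserved_cpts: Sequence[str] = (),
) -> EncoderSpec:
    """Build the frozen encoder spec from a master corpus.

    CPT codes present in fewer than ``min_claims`` distinct claims are dropped.
    ``reserved_cpts`` are added to the vocabulary unconditionally (claim count
    zero if unseen) — these are the dimensions reserved for out-of-sample
    procedure codes that evaluation sets may inject.  All ICD categories seen
    in the corpus are retained.
    """
    if len(master_corpus) == 0:
        raise EncodingConfigError("cannot build an encoder spec from an empty corpus")
    counts = count_cpt_claims(master_corpus)
    reserved = frozenset(c.strip().upper() for c in reserved_cpts)
    retained = {c for c, n in counts.items() if n >= min_claims} | reserved
    if not retained:
        raise EncodingConfigError(
            f"min_claims={min_claims} filters out every CPT code "
            f"(max observed count {max(counts.values())}); lower min_claims"
        )
    icds = sorted({cat for claim in master_corpus for cat in claim.icd_categories})
    vocab = CodeVocabulary(
        cpt_codes=tuple(sorted(retained)),
        icd_categories=tuple(icds),
        cpt_claim_counts={c: counts.get(c, 0) for c in sorted(retained)},
        reserved_cpts=reserved,
    )
    return EncoderSpec(vocabulary=vocab, min_claims=min_claims)


def encode_claim(claim: Claim, spec: EncoderSpec) -> EncodedClaim | None:
    """Encode one claim into the fixed binary layout.

    Procedure codes absent from the vocabulary (filtered as rare) are dropped
    from the encoding; repeated units of one procedure collapse to a single
    active bit.  Returns ``None`` (a skip signal) when no CPT code or no ICD
    category of the claim is encodable — such claims are excluded from
    training and scoring.
    """
    cpt_index = spec.cpt_index
    positions = sorted({cpt_index[c] for c in claim.cpt_codes if c in cpt_index})
    if not positions:
        logger.warning("claim %s: no encodable CPT codes, skipping", claim.claim_id)
        return None
    icd_index = spec.icd_index
    icd_positions = sorted({icd_index[c] for c in claim.icd_categories if c in icd_index})
    if not icd_positions:
        logger.warning("claim %s: no encodable ICD categories, skipping", claim.claim_id)
        return None

    vec = np.zeros(spec.feature_length, dtype=np.uint8)
    vec[positions] = 1
    vec[icd_positions] = 1
    vec[spec.age_offset + bucket_age(claim.age_years)] = 1
    vec[spec.gender_offset + spec.gender_levels.index(claim.gender)] = 1
    return EncodedClaim(claim_id=claim.claim_id, vector=vec, cpt_positions=tuple(positions))


def encode_corpus(corpus: ClaimsCorpus, spec: EncoderSpec) -> EncodedCorpus:
    """Encode every claim in order, collecting skip signals."""
    encoded, skipped = [], []
    for claim in corpus:
        enc = encode_claim(claim, spec)
        if enc is None:
            skipped.append(claim.claim_id)
        else:
            encoded.append(enc)
    if skipped:
        logger.info("encode_corpus: skipped %d of %d claims", len(skipped), len(corpus))
    return EncodedCorpus(claims=encoded, skipped_claim_ids=skipped, spec=spec)


def decode_claim(encoded: EncodedClaim, spec: EncoderSpec) -> dict:
    """Invert an encoding back to code sets, age bucket and gender."""
    vec = encoded.vector
    cpts = {spec.vocabulary.cpt_codes[i] for i in range(spec.n_cpt) if vec[i]}
    icds = {
        spec.vocabulary.icd_categories[i - spec.n_cpt]
        for i in range(spec.n_cpt, spec.n_cpt + spec.n_icd)
        if vec[i]
    }
    age_block = vec[spec.age_offset : spec.age_offset + spec.n_age_buckets]
    gender_block = vec[spec.gender_offset :]
    return {
        "cpt_codes": cpts,
        "icd_categories": icds,
        "age_bucket": int(np.argmax(age_block)),
        "gender": spec.gender_levels[int(np.argmax(gender_block))],
    }
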