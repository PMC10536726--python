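"""Synthetic outpatient-claims generator and evaluation outlier injection.

Real Medicare claims cannot be redistributed, so this module generates corpora
that emulate their statistical structure: each diagnosis category owns a pool
of plausible procedure codes, procedure frequencies are long-tailed (Zipf),
demographics (age bucket, gender) are conditioned on the primary diagnosis,
and a claim draws 1-3 diagnoses plus 1-6 procedures from the union of its
diagnoses' pools.

A configurable number of *reserved* procedure codes belong to no pool and are
never emitted in normal claims.  They implement out-of-sample evaluation
deterministically: reserved codes own feature dimensions (via the encoder's
reserved-code mechanism) yet have zero occurrences in any training corpus, so
injecting them into held-out claims creates ground-truth outliers that the
training data has never exhibited.

Two injection modes mirror the two kinds of evaluation sets used for this
problem: ``out_of_sample`` adds reserved codes, and ``context_mismatch`` adds
in-vocabulary codes drawn from pools of diagnoses the claim does *not* carry —
a stand-in for human-annotated overutilization, which is harder because the
injected codes were seen during training, just never in this context.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .claims_data import AGE_BUCKET_EDGES, GENDERS, Claim, ClaimsCorpus

AGE_BUCKET_RANGES = ((0, 17), (18, 38), (39, 59), (60, 80), (81, 100))


class WorldConfigError(ValueError):
    """The synthetic-world configuration is unsatisfiable."""


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Configuration of the synthetic claims universe.

    Defaults are desk-scale: 40 diagnosis categories and 400 procedure codes
    (20 of them reserved for out-of-sample injection), pools of 8-16
    procedures per diagnosis, claims carrying 1-3 diagnoses and 1-6
    procedures, and a Zipf exponent of 1.1 giving the long-tailed code
    frequency distribution seen in claims data.
    """

    n_icd_categories: int = 40
    n_cpt_codes: int = 400
    n_reserved_oos_cpts: int = 20
    cpts_per_icd: tuple[int, int] = (8, 16)
    claim_cpt_count: tuple[int, int] = (1, 6)
    claim_icd_count: tuple[int, int] = (1, 3)
    code_frequency_skew: float = 1.1
    demographic_concentration: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.claim_icd_count[0] <= self.claim_icd_count[1] <= 3):
            raise WorldConfigError("claim_icd_count must be a sub-range of [1, 3]")
        if self.claim_cpt_count[0] < 1 or self.claim_cpt_count[0] > self.claim_cpt_count[1]:
            raise WorldConfigError("invalid claim_cpt_count range")
        if self.n_reserved_oos_cpts < 0 or self.n_reserved_oos_cpts >= self.n_cpt_codes:
            raise WorldConfigError("n_reserved_oos_cpts must be in [0, n_cpt_codes)")
        if self.cpts_per_icd[0] > self.n_cpt_codes - self.n_reserved_oos_cpts:
            raise WorldConfigError(
                f"cpts_per_icd={self.cpts_per_icd} exceeds the "
                f"{self.n_cpt_codes - self.n_reserved_oos_cpts} non-reserved CPT codes"
            )


@dataclass(frozen=True)
class World:
    """A realized claims universe: code lists, pools, and conditional laws."""

    spec: SyntheticWorldSpec
    icd_categories: tuple[str, ...]
    cpt_codes: tuple[str, ...]
    reserved_cpts: tuple[str, ...]
    pools: dict[str, tuple[str, ...]]  # ICD category -> its CPT pool
    cpt_weights: dict[str, float]  # Zipf sampling weight per normal CPT
    icd_probs: dict[str, float]  # marginal diagnosis-category law
    age_dist: dict[str, np.ndarray]  # per-ICD multinomial over 5 age buckets
    gender_dist: dict[str, np.ndarray]  # per-ICD multinomial over 3 genders

    @property
    def normal_cpts(self) -> tuple[str, ...]:
        reserved = set(self.reserved_cpts)
        return tuple(c for c in self.cpt_codes if c not in reserved)


@dataclass(frozen=True)
class InjectionSpec:
    """How to turn a clean held-out corpus into a labeled outlier test set.

    ``outlier_fraction`` defaults reflect the evaluation protocol this module
    emulates: 0.27 for out-of-sample sets (0.20 for the large-scale variant)
    and 0.30 for the annotated-set stand-in.  Half of the outlier claims get
    one injected code and half get two (an odd count gives the extra claim
    one).
    """

    outlier_fraction: float = 0.27
    mode: Literal["out_of_sample", "context_mismatch"] = "out_of_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.outlier_fraction < 1.0:
            raise WorldConfigError("outlier_fraction must lie strictly between 0 and 1")


def _icd_names(n: int) -> list[str]:
    """Synthetic ICD-10-style category codes: A00, A01, ... Z99."""
    if n > 2600:
        raise WorldConfigError("at most 2600 synthetic ICD categories supported")
    letters = string.ascii_uppercase
    return [f"{letters[i // 100]}{i % 100:02d}" for i in range(n)]


def _cpt_names(n_normal: int, n_reserved: int) -> tuple[list[str], list[str]]:
    """Synthetic 5-character procedure codes; reserved ones are X-prefixed."""
    normal = [f"{10000 + i:05d}" for i in range(n_normal)]
    reserved = [f"X{9000 + i:04d}" for i in range(n_reserved)]
    return normal, reserved


def generate_world(spec: SyntheticWorldSpec) -> World:
    """Realize a claims universe from its configuration, deterministically.

    Each diagnosis category receives a procedure pool sampled (without
    replacement, Zipf-weighted so common codes recur across pools) from the
    non-reserved codes, a Zipf marginal over diagnosis categories, and
    Dirichlet-drawn age/gender conditionals.  Reserved codes belong to no pool.
    """
    rng = np.random.default_rng(spec.seed)
    icds = _icd_names(spec.n_icd_categories)
    normal, reserved = _cpt_names(spec.n_cpt_codes - spec.n_reserved_oos_cpts, spec.n_reserved_oos_cpts)

    # Long-tailed global popularity for normal codes, in a shuffled rank order
    # so lexicographic position carries no frequency information.
    ranks = rng.permutation(len(normal)) + 1
    weights = ranks.astype(np.float64) ** -spec.code_frequency_skew
    cpt_weights = {c: float(w) for c, w in zip(normal, weights)}

    icd_ranks = rng.permutation(len(icds)) + 1
    icd_w = icd_ranks.astype(np.float64) ** -spec.code_frequency_skew
    icd_probs = {c: float(w / icd_w.sum()) for c, w in zip(icds, icd_w)}

    p_pool = weights / weights.sum()
    pools: dict[str, tuple[str, ...]] = {}
    age_dist: dict[str, np.ndarray] = {}
    gender_dist: dict[str, np.ndarray] = {}
    lo, hi = spec.cpts_per_icd
    alpha = spec.demographic_concentration
    for icd in icds:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(normal), size=size, replace=False, p=p_pool)
        pools[icd] = tuple(sorted(normal[i] for i in members))
        age_dist[icd] = rng.dirichlet(np.full(5, alpha))
        gender_dist[icd] = rng.dirichlet(np.full(3, alpha))

    return World(
        spec=spec,
        icd_categories=tuple(icds),
        cpt_codes=tuple(sorted(normal + reserved)),
        reserved_cpts=tuple(reserved),
        pools=pools,
        cpt_weights=cpt_weights,
        icd_probs=icd_probs,
        age_dist=age_dist,
        gender_dist=gender_dist,
    )


def _draw_claim(world: World, rng: np.random.Generator, claim_id: str) -> Claim:
    spec = world.spec
    icds = list(world.icd_categories)
    p_icd = np.array([world.icd_probs[c] for c in icds])

    n_icd = int(rng.integers(spec.claim_icd_count[0], spec.claim_icd_count[1] + 1))
    chosen_idx = rng.choice(len(icds), size=n_icd, replace=False, p=p_icd)
    chosen = [icds[i] for i in chosen_idx]
    primary = chosen[0]

    pool = sorted(set().union(*(world.pools[c] for c in chosen)))
    w = np.array([world.cpt_weights[c] for c in pool])
    n_cpt = int(rng.integers(spec.claim_cpt_count[0], spec.claim_cpt_count[1] + 1))
    n_cpt = min(n_cpt, len(pool))
    cpt_idx = rng.choice(len(pool), size=n_cpt, replace=False, p=w / w.sum())
    cpts = tuple(pool[i] for i in cpt_idx)

    bucket = int(rng.choice(5, p=world.age_dist[primary]))
    a_lo, a_hi = AGE_BUCKET_RANGES[bucket]
    age = int(rng.integers(a_lo, a_hi + 1))
    gender = GENDERS[int(rng.choice(3, p=world.gender_dist[primary]))]

    return Claim(
        claim_id=claim_id,
        icd_categories=tuple(chosen),
        cpt_codes=cpts,
        age_years=age,
        gender=gender,
    )


def generate_corpus(
    world: World,
    n_claims: int,
    seed: int,
    id_prefix: str = "S",
    id_start: int = 0,
    provenance: str = "synthetic",
) -> ClaimsCorpus:
    """Draw ``n_claims`` claims from the world's generative law.

    Claim identifiers are ``{id_prefix}{id_start+i:08d}``; disjoint prefix or
    start ranges keep train/test corpora free of shared claims.
    """
    if n_claims <= 0:
        raise WorldConfigError(f"n_claims must be positive, got {n_claims}")
    rng = np.random.default_rng(seed)
    claims = [
        _draw_claim(world, rng, f"{id_prefix}{id_start + i:08d}") for i in range(n_claims)
    ]
    return ClaimsCorpus(claims=claims, provenance=provenance)


def eligible_mismatch_codes(claim: Claim, world: World) -> tuple[str, ...]:
    """In-vocabulary codes foreign to all of the claim's own diagnosis pools."""
    own = set().union(*(world.pools[c] for c in claim.icd_categories if c in world.pools))
    foreign = set()
    for icd, pool in world.pools.items():
        if icd not in claim.icd_categories:
            foreign.update(pool)
    return tuple(sorted(foreign - own))


def inject_outliers(
    test_corpus: ClaimsCorpus,
    world: World,
    inj: InjectionSpec,
) -> tuple[ClaimsCorpus, np.ndarray]:
    """Add outlier procedure codes to a fraction of the claims.

    Exactly ``round(outlier_fraction * n)`` claims are injected; half receive
    one added code and half two (odd counts give the extra claim one).  Mode
    ``out_of_sample`` draws from the world's reserved codes, which appear in
    no training corpus; ``context_mismatch`` draws codes from pools of
    diagnoses the claim does not carry.  Codes are only ever added, never
    removed.  Returns the modified corpus and a 0/1 label per claim (1 = the
    claim was injected, hence contains at least one outlier procedure).
    """
    n = len(test_corpus)
    rng = np.random.default_rng(inj.seed)
    n_outliers = int(round(inj.outlier_fraction * n))
    if inj.mode == "out_of_sample" and len(world.reserved_cpts) < 2:
        raise WorldConfigError("out_of_sample injection needs >= 2 reserved codes")

    chosen = rng.choice(n, size=n_outliers, replace=False)
    n_single = n_outliers - n_outliers // 2  # odd count -> extra claim gets 1 code
    codes_per_claim = {int(ix): (1 if k < n_single else 2) for k, ix in enumerate(chosen)}

    labels = np.zeros(n, dtype=np.int64)
    new_claims: list[Claim] = []
    for i, claim in enumerate(test_corpus):
        k = codes_per_claim.get(i)
        if k is None:
            new_claims.append(claim)
            continue
        if inj.mode == "out_of_sample":
            eligible = world.reserved_cpts
        else:
            eligible = eligible_mismatch_codes(claim, world)
        if len(eligible) < k:
            raise WorldConfigError(
                f"claim {claim.claim_id}: only {len(eligible)} eligible "
                f"{inj.mode} codes, need {k}"
            )
        added = rng.choice(len(eligible), size=k, replace=False)
        new_claims.append(claim.with_extra_cpts([eligible[j] for j in added]))
        labels[i] = 1

    corpus = ClaimsCorpus(claims=new_claims, provenance=f"{test_corpus.provenance}+{inj.mode}")
    return corpus, labels


def write_labels(corpus: ClaimsCorpus, labels: np.ndarray, path: str | Path) -> None:
    """Persist ground-truth labels as a two-column table (claim_id, is_outlier)."""
    pd.DataFrame({"claim_id": corpus.claim_ids, "is_outlier": labels.astype(int)}).to_csv(
        path, index=False
    )


def load_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"claim_id": str, "is_outlier": int})
    return dict(zip(df["claim_id"], df["is_outlier"]))
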