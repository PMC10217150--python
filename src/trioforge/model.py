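"""Core data model shared by every pipeline stage.

Coordinates are 1-based throughout (VCF convention). Chromosome labels are
stored without a ``chr`` prefix; both dialects are accepted on input and
normalized at ingestion.

Genotypes are held in a dense integer matrix (variants x samples) using the
codes in :data:`GT_CODES`; per-site read depths live in a parallel matrix.
This keeps a 5,000-site x 64-sample cohort comfortably in memory and lets
the simulator and the segregation classifier work on numpy arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

# Genotype categories. ``missing`` covers ./. calls; it is never imputed.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_CODES = {"hom_ref": HOM_REF, "het": HET, "hom_alt": HOM_ALT, "missing": MISSING}
GT_NAMES = {v: k for k, v in GT_CODES.items()}

CONSEQUENCES = ("missense", "stop_gained", "stop_lost", "frameshift", "synonymous", "other")
LOF_CONSEQUENCES = frozenset({"stop_gained", "stop_lost", "frameshift"})

VALID_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix and validate the chromosome label."""
    c = label[3:] if label.lower().startswith("chr") else label
    if c == "MT" or c == "M":
        c = "MT"
    elif c not in VALID_CHROMS:
        raise ValueError(f"unrecognized chromosome label: {label!r}")
    return c


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized single-alt genomic substitution or small indel.

    ``(chrom, pos, ref, alt)`` uniquely keys a variant within a cohort;
    multiallelic VCF records are split upstream so ``alt`` is always a
    single allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    hgvs_g: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class AnnotationProfile:
    """Per-variant annotation fields carried as pipeline input.

    ``af_pop`` is the population alternate-allele frequency from a reference
    database (gnomAD-style); ``None`` means the allele was never observed
    there, which the filter cascade treats as frequency 0. Categorical
    predictor calls use ``None`` for "absent".
    """

    af_pop: Optional[float] = None
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    sift: Optional[str] = None            # "deleterious" | "tolerated" | None
    polyphen: Optional[str] = None        # "damaging" | "benign" | None
    mutation_taster: Optional[str] = None  # "disease_causing" | "polymorphism" | None
    consequence: str = "other"
    clinvar: Optional[str] = None         # "pathogenic" | "benign" | "vus" | None

    def __post_init__(self) -> None:
        if self.af_pop is not None and not (0.0 <= self.af_pop <= 1.0):
            raise ValueError(f"af_pop must lie in [0, 1], got {self.af_pop}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be >= 0")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid call for one sample at one site."""

    sample_id: str
    gt: str            # hom_ref | het | hom_alt | missing
    depth: int = 0

    def __post_init__(self) -> None:
        if self.gt not in GT_CODES:
            raise ValueError(f"unknown genotype category {self.gt!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class Family:
    """A proband-parent trio, optionally extended by unaffected siblings."""

    family_id: str
    proband: str
    father: str
    mother: str
    siblings: tuple[str, ...] = ()
    proband_sex: str = "unknown"          # male | female | unknown
    sexes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {self.proband, self.father, self.mother}
        if len(ids) != 3:
            raise ValueError(f"family {self.family_id}: proband/father/mother must be distinct")

    @property
    def members(self) -> tuple[str, ...]:
        return (self.proband, self.father, self.mother) + tuple(self.siblings)


class CohortTable:
    """Joint container for variants, annotations, genotypes and pedigrees.

    Attributes
    ----------
    variants : list[Variant]
        Site list; keys are unique.
    profiles : list[AnnotationProfile | None]
        Parallel to ``variants``.
    samples : list[str]
        Column order of the genotype matrix.
    gt : numpy.ndarray, int8, shape (n_variants, n_samples)
        Genotype codes (0 hom_ref, 1 het, 2 hom_alt, -1 missing).
    depth : numpy.ndarray, int32, same shape
        Site read depth per sample.
    families : list[Family]
    """

    def __init__(
        self,
        variants: list[Variant],
        samples: list[str],
        gt: np.ndarray,
        depth: Optional[np.ndarray] = None,
        profiles: Optional[list[Optional[AnnotationProfile]]] = None,
        families: Optional[list[Family]] = None,
    ) -> None:
        n, m = len(variants), len(samples)
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (n, m):
            raise ValueError(f"gt shape {gt.shape} does not match ({n}, {m})")
        if depth is None:
            depth = np.zeros((n, m), dtype=np.int32)
        depth = np.asarray(depth, dtype=np.int32)
        if depth.shape != (n, m):
            raise ValueError("depth shape mismatch")
        if profiles is None:
            profiles = [None] * n
        if len(profiles) != n:
            raise ValueError("profiles length mismatch")
        keys = [v.key for v in variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys in cohort")
        self.variants = list(variants)
        self.samples = list(samples)
        self.gt = gt
        self.depth = depth
        self.profiles = list(profiles)
        self.families = list(families or [])
        self._sample_index = {s: j for j, s in enumerate(self.samples)}
        self._variant_index = {k: i for i, k in enumerate(keys)}
        self._check_families()

    def _check_families(self) -> None:
        for fam in self.families:
            for sid in fam.members:
                if sid not in self._sample_index:
                    raise ValueError(
                        f"family {fam.family_id}: sample {sid!r} absent from genotype matrix"
                    )

    # -- lookups -----------------------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def variant_index(self, key: tuple[str, int, str, str]) -> int:
        try:
            return self._variant_index[key]
        except KeyError:
            raise KeyError(f"unknown variant {key!r}") from None

    def genotype(self, variant_idx: int, sample_id: str) -> GenotypeCall:
        j = self.sample_index(sample_id)
        return GenotypeCall(
            sample_id=sample_id,
            gt=GT_NAMES[int(self.gt[variant_idx, j])],
            depth=int(self.depth[variant_idx, j]),
        )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "CohortTable":
        return CohortTable(
            variants=list(self.variants),
            samples=list(self.samples),
            gt=self.gt.copy(),
            depth=self.depth.copy(),
            profiles=list(self.profiles),
            families=list(self.families),
        )

    def equals(self, other: "CohortTable") -> bool:
        """Field-by-field equality (used by round-trip tests)."""
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.depth, other.depth)
            and self.profiles == other.profiles
            and self.families == other.families
        )


def merge_fragments(fragments: Iterable[CohortTable]) -> CohortTable:
    """Concatenate per-family cohort fragments sharing a sample universe.

    Sample sets must be disjoint or identical across fragments; variant keys
    are unioned with genotypes aligned (absent combinations become missing).
    """
    frags = list(fragments)
    if not frags:
        raise ValueError("no fragments to merge")
    if len(frags) == 1:
        return frags[0]
    samples: list[str] = []
    for f in frags:
        for s in f.samples:
            if s not in samples:
                samples.append(s)
    keys: list[tuple[str, int, str, str]] = []
    var_by_key: dict[tuple, Variant] = {}
    prof_by_key: dict[tuple, Optional[AnnotationProfile]] = {}
    for f in frags:
        for v, p in zip(f.variants, f.profiles):
            if v.key not in var_by_key:
                keys.append(v.key)
                var_by_key[v.key] = v
                prof_by_key[v.key] = p
    gt = np.full((len(keys), len(samples)), MISSING, dtype=np.int8)
    dp = np.zeros((len(keys), len(samples)), dtype=np.int32)
    col = {s: j for j, s in enumerate(samples)}
    row = {k: i for i, k in enumerate(keys)}
    for f in frags:
        rows = [row[v.key] for v in f.variants]
        cols = [col[s] for s in f.samples]
        gt[np.ix_(rows, cols)] = f.gt
        dp[np.ix_(rows, cols)] = f.depth
    families = [fam for f in frags for fam in f.families]
    return CohortTable(
        variants=[var_by_key[k] for k in keys],
        samples=samples,
        gt=gt,
        depth=dp,
        profiles=[prof_by_key[k] for k in keys],
        families=families,
    )
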