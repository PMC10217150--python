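"""Pedigree-structured genotype simulator with a recorded truth set.

The generator emulates a 16-family trio/quad exome design: a shared site
list (joint-VCF style), parental genotypes drawn from a population allele
frequency under Hardy-Weinberg, children receiving one allele per parent
uniformly at random, planted de novo heterozygous missense variants and
recessive-homozygous configurations with rare/deleterious annotations, and
an optional independent genotyping-error process.

Truth bookkeeping: the simulator knows every transmission it drew, so the
truth set records, per (variant, family), not only the planted events but
also the segregation pattern realized by chance at background sites — in
particular a common-allele het x het parent pair whose child drew both
alternate alleles is a genuine recessive-homozygous configuration and is
labelled as such. Recovery metrics for the segregation classifier are
defined against these labels (a correct call at such a site is not a false
discovery).

Sex chromosomes are simulated as autosomes (proband sex is recorded but no
hemizygosity is modelled); planted candidates are autosomal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotationProfile,
    CohortTable,
    Family,
    Variant,
)

_BASES = np.array(list("ACGT"))

#: Per-exome consequence-class proportions, derived from the per-proband
#: class means of the reference cohort (means over 16 probands of a
#: 840,667-variant exome: missense 10,764.5; frameshift 660.75;
#: stop gained 153.75; stop lost 29.3125); the remainder is "other".
DEFAULT_CLASS_PROPORTIONS = {
    "missense": 10764.5 / 840667.0,
    "frameshift": 660.75 / 840667.0,
    "stop_gained": 153.75 / 840667.0,
    "stop_lost": 29.3125 / 840667.0,
}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the reference design: 16 families, all quads (64
    samples), 11 male probands, site depth centred on 250x. The desk-scale
    site count is 5,000 shared sites; the study-scale figure (840,667) is
    reachable by configuration but not a default.
    """

    n_families: int = 16
    n_quads: int = 16
    n_male_probands: int = 11
    variants_per_exome: int = 5000
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    n_de_novo_per_proband: int = 2
    n_recessive_per_proband: int = 2
    af_common_range: tuple[float, float] = (0.05, 0.5)
    af_rare_range: tuple[float, float] = (1e-6, 1e-2)
    rare_fraction: float = 0.25
    candidate_af_max: float = 1e-4
    genotyping_error_rate: float = 0.0
    depth_mean: float = 250.0
    depth_dispersion: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_quads > self.n_families:
            raise ConfigError("n_quads cannot exceed n_families")
        if self.n_male_probands > self.n_families:
            raise ConfigError("n_male_probands cannot exceed n_families")
        if sum(self.class_proportions.values()) > 1.0 + 1e-12:
            raise ConfigError("class proportions must sum to <= 1")
        if not (0.0 <= self.genotyping_error_rate <= 1.0):
            raise ConfigError("genotyping_error_rate must lie in [0, 1]")
        if not (0.0 <= self.rare_fraction <= 1.0):
            raise ConfigError("rare_fraction must lie in [0, 1]")
        n_planted = self.n_families * (self.n_de_novo_per_proband + self.n_recessive_per_proband)
        if self.variants_per_exome < n_planted:
            raise ConfigError(
                f"variants_per_exome={self.variants_per_exome} cannot hold "
                f"{n_planted} planted sites"
            )
        if self.n_recessive_per_proband > 0 and self.candidate_af_max <= 0:
            raise ConfigError("recessive sites demanded but candidate_af_max is 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth model parameters must be positive")

    @property
    def n_samples(self) -> int:
        return 3 * (self.n_families - self.n_quads) + 4 * self.n_quads


@dataclass
class TruthSet:
    """Ground-truth segregation labels and planted-candidate registry.

    ``labels`` records every (variant key, family id) whose realized pattern
    is not plain background: planted events plus chance configurations the
    generator drew (inherited origins, background recessive-homozygous).
    ``planted`` is the subset that was deliberately injected.
    """

    labels: dict = field(default_factory=dict)     # (key, fam) -> label
    planted: dict = field(default_factory=dict)    # (key, fam) -> "de_novo"|"recessive_hom"
    candidate_genes: set = field(default_factory=set)
    site_af: dict = field(default_factory=dict)    # key -> simulated population af

    def pairs_with_label(self, label: str) -> set:
        return {pair for pair, lab in self.labels.items() if lab == label}

    def planted_pairs(self, label: str) -> set:
        return {pair for pair, lab in self.planted.items() if lab == label}


def _site_coords(n: int) -> list[tuple[str, int]]:
    """Deterministic unique autosomal coordinates for n sites."""
    out = []
    for i in range(n):
        chrom = str((i % 22) + 1)
        pos = 1_000_000 + (i // 22) * 211 + 1
        out.append((chrom, pos))
    return out


def _draw_ref_alt(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_i], _BASES[alt_i]


def _build_families(cfg: SimulationConfig) -> list[Family]:
    families = []
    for f in range(cfg.n_families):
        fid = f"F{f + 1:02d}"
        proband, father, mother = f"{fid}_P", f"{fid}_FA", f"{fid}_MO"
        is_quad = f < cfg.n_quads
        sibs = (f"{fid}_S1",) if is_quad else ()
        psex = "male" if f < cfg.n_male_probands else "female"
        sexes = {proband: psex, father: "male", mother: "female"}
        for s in sibs:
            sexes[s] = "female" if f % 2 else "male"
        families.append(Family(
            family_id=fid, proband=proband, father=father, mother=mother,
            siblings=sibs, proband_sex=psex, sexes=sexes,
        ))
    return families


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, TruthSet]:
    """Generate genotypes for the configured cohort; deterministic per seed.

    Returns the cohort (annotations not yet attached; see
    :func:`inject_annotations`) and its truth set. The site list is shared
    across the cohort, so the per-exome site count equals
    ``variants_per_exome`` exactly.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    families = _build_families(cfg)
    samples = [sid for fam in families for sid in fam.members]
    col = {s: j for j, s in enumerate(samples)}
    n_fam = cfg.n_families

    n_planted = n_fam * (cfg.n_de_novo_per_proband + cfg.n_recessive_per_proband)
    n_bg = cfg.variants_per_exome - n_planted
    coords = _site_coords(cfg.variants_per_exome)
    refs, alts = _draw_ref_alt(rng, cfg.variants_per_exome)

    # population allele frequency mixture for background sites
    is_rare = rng.random(n_bg) < cfg.rare_fraction
    lo, hi = cfg.af_rare_range
    af_bg = np.where(
        is_rare,
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_bg)),
        rng.uniform(*cfg.af_common_range, size=n_bg),
    )

    gt = np.zeros((cfg.variants_per_exome, len(samples)), dtype=np.int8)
    truth = TruthSet()

    # --- background transmission, vectorized over (site, family) ----------
    p = af_bg[:, None, None]
    fa_alleles = (rng.random((n_bg, n_fam, 2)) < p).astype(np.int8)
    mo_alleles = (rng.random((n_bg, n_fam, 2)) < p).astype(np.int8)
    fa_gt = fa_alleles.sum(axis=2)
    mo_gt = mo_alleles.sum(axis=2)

    site_idx = np.arange(n_bg)[:, None]
    fam_idx = np.arange(n_fam)[None, :]

    def transmit():
        pick_f = rng.integers(0, 2, size=(n_bg, n_fam))
        pick_m = rng.integers(0, 2, size=(n_bg, n_fam))
        from_f = fa_alleles[site_idx, fam_idx, pick_f]
        from_m = mo_alleles[site_idx, fam_idx, pick_m]
        return from_f, from_m

    pb_from_f, pb_from_m = transmit()
    pb_gt = pb_from_f + pb_from_m

    sib_gt = np.full((n_bg, n_fam), -9, dtype=np.int8)
    quad_mask = np.array([bool(fam.siblings) for fam in families])
    sb_from_f, sb_from_m = transmit()
    sib_all = sb_from_f + sb_from_m

    for f, fam in enumerate(families):
        gt[:n_bg, col[fam.father]] = fa_gt[:, f]
        gt[:n_bg, col[fam.mother]] = mo_gt[:, f]
        gt[:n_bg, col[fam.proband]] = pb_gt[:, f]
        if fam.siblings:
            gt[:n_bg, col[fam.siblings[0]]] = sib_all[:, f]
            sib_gt[:, f] = sib_all[:, f]

    # --- background truth labels ------------------------------------------
    # inherited origin of a het proband allele; chance recessive patterns
    het_pb = pb_gt == 1
    paternal = het_pb & (pb_from_f == 1)
    maternal = het_pb & (pb_from_m == 1)
    rec_bg = (fa_gt == 1) & (mo_gt == 1) & (pb_gt == 2)
    sib_ok = ~quad_mask[None, :] | (sib_gt != 2)
    rec_bg &= sib_ok

    genes_bg = [f"BG{(i % max(n_bg // 5, 1)):05d}" for i in range(n_bg)]
    variants: list[Variant] = []
    for i in range(n_bg):
        c, pos = coords[i]
        variants.append(Variant(chrom=c, pos=pos, ref=str(refs[i]), alt=str(alts[i]), gene=genes_bg[i]))

    fam_ids = [fam.family_id for fam in families]
    for i, f in zip(*np.nonzero(paternal)):
        truth.labels[(variants[i].key, fam_ids[f])] = "inherited_paternal"
    for i, f in zip(*np.nonzero(maternal & ~paternal)):
        truth.labels[(variants[i].key, fam_ids[f])] = "inherited_maternal"
    for i, f in zip(*np.nonzero(rec_bg)):
        truth.labels[(variants[i].key, fam_ids[f])] = "recessive_hom"
    for i in range(n_bg):
        truth.site_af[variants[i].key] = float(af_bg[i])

    # --- planted events ----------------------------------------------------
    row = n_bg
    cand_counter = 0
    for f, fam in enumerate(families):
        for _ in range(cfg.n_de_novo_per_proband):
            c, pos = coords[row]
            gene = f"CAND{cand_counter:04d}"
            cand_counter += 1
            v = Variant(chrom=c, pos=pos, ref=str(refs[row]), alt=str(alts[row]), gene=gene)
            variants.append(v)
            gt[row, col[fam.proband]] = HET
            # parents/siblings stay hom_ref (matrix is zero-initialized)
            truth.labels[(v.key, fam.family_id)] = "de_novo"
            truth.planted[(v.key, fam.family_id)] = "de_novo"
            truth.candidate_genes.add(gene)
            row += 1
        for _ in range(cfg.n_recessive_per_proband):
            c, pos = coords[row]
            gene = f"CAND{cand_counter:04d}"
            cand_counter += 1
            v = Variant(chrom=c, pos=pos, ref=str(refs[row]), alt=str(alts[row]), gene=gene)
            variants.append(v)
            gt[row, col[fam.proband]] = HOM_ALT
            gt[row, col[fam.father]] = HET
            gt[row, col[fam.mother]] = HET
            for s in fam.siblings:
                # conditioned on not hom_alt: het with prob 2/3, hom_ref 1/3
                gt[row, col[s]] = HET if rng.random() < 2.0 / 3.0 else HOM_REF
            truth.labels[(v.key, fam.family_id)] = "recessive_hom"
            truth.planted[(v.key, fam.family_id)] = "recessive_hom"
            truth.candidate_genes.add(gene)
            row += 1

    # --- depth: negative binomial around the configured mean ---------------
    k = cfg.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + cfg.depth_mean), size=gt.shape).astype(np.int32)

    cohort = CohortTable(
        variants=variants, samples=samples, gt=gt, depth=depth, families=families,
    )

    if cfg.genotyping_error_rate > 0:
        cohort = perturb_genotypes(cohort, cfg.genotyping_error_rate, seed=int(rng.integers(2**31)))
    return cohort, truth


def inject_annotations(
    cohort: CohortTable,
    truth: TruthSet,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> CohortTable:
    """Attach an AnnotationProfile to every variant.

    Planted candidates receive a rare population frequency (log-uniform up
    to ``candidate_af_max``), high CADD/GERP and unanimous deleterious
    predictor calls; planted de novo sites are missense (the design's focus
    class). Background sites reuse the allele frequency that generated
    their genotypes and draw predictor calls from mostly-benign margins;
    their consequence class follows ``class_proportions``.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    planted_keys = {key for (key, _fam) in truth.planted}

    classes = list(config.class_proportions) + ["other"]
    probs = list(config.class_proportions.values())
    probs.append(max(0.0, 1.0 - sum(probs)))
    probs = np.asarray(probs) / np.sum(probs)

    profiles: list[AnnotationProfile] = []
    for v in cohort.variants:
        if v.key in planted_keys:
            af = float(np.exp(rng.uniform(np.log(1e-6), np.log(config.candidate_af_max))))
            profiles.append(AnnotationProfile(
                af_pop=af,
                cadd_phred=float(rng.uniform(25, 45)),
                gerp=float(rng.uniform(3, 6)),
                sift="deleterious",
                polyphen="damaging",
                mutation_taster="disease_causing",
                consequence="missense",
                clinvar=None,
            ))
            truth.site_af[v.key] = af
        else:
            csq = str(rng.choice(classes, p=probs))
            sift = str(rng.choice(["deleterious", "tolerated", "absent"], p=[0.1, 0.7, 0.2]))
            poly = str(rng.choice(["damaging", "benign", "absent"], p=[0.1, 0.7, 0.2]))
            mt = str(rng.choice(["disease_causing", "polymorphism", "absent"], p=[0.05, 0.75, 0.2]))
            profiles.append(AnnotationProfile(
                af_pop=float(truth.site_af.get(v.key, rng.uniform(0.05, 0.5))),
                cadd_phred=float(rng.uniform(0, 30)),
                gerp=float(rng.normal(0, 2)),
                sift=None if sift == "absent" else sift,
                polyphen=None if poly == "absent" else poly,
                mutation_taster=None if mt == "absent" else mt,
                consequence=csq,
                clinvar=None,
            ))
    cohort.profiles = profiles
    return cohort


def perturb_genotypes(cohort: CohortTable, error_rate: float, seed: int = 0) -> CohortTable:
    """Independently corrupt genotypes at the given rate; truth is unchanged.

    Each perturbed call is replaced by a uniformly chosen *different*
    category among {hom_ref, het, hom_alt}; missing calls, if any, become a
    uniform called genotype when hit.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ConfigError("error_rate must lie in [0, 1]")
    out = cohort.copy()
    if error_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    hit = rng.random(out.gt.shape) < error_rate
    shift = rng.integers(1, 3, size=out.gt.shape)  # +1 or +2 mod 3 => different
    g = out.gt
    perturbed = np.where(g == MISSING, rng.integers(0, 3, size=g.shape), (g + shift) % 3)
    out.gt = np.where(hit, perturbed, g).astype(np.int8)
    return out


def generate_cohort(config: SimulationConfig) -> tuple[CohortTable, TruthSet]:
    """simulate_cohort + inject_annotations in one call."""
    cohort, truth = simulate_cohort(config)
    cohort = inject_annotations(cohort, truth, config)
    return cohort, truth
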