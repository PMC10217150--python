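"""Packaged reference tables and the worked-example cohort.

Four small TSVs ship with the package under ``trioforge/data``:

``cpc_cohort_counts.tsv``
    Pooled variant-class counts for a 16-proband / 46-control exome cohort,
    with the published group means and pooled percentages for golden
    comparison.
``cpc_assay_plex.tsv``
    A 12-SNP genotyping plex (37 samples) with no-call counts and published
    call frequencies.
``cpc_enrichment.tsv``
    106 gene-ontology terms with published (p, adjusted p, z, combined)
    enrichment statistics.
``cpc_rare_variants.tsv``
    The three extremely rare candidate variants (MUC5B, FRG1, TAF1B) with
    their published annotations and carrier probands. The MUC5B carrier
    list is a synthetic completion: the published record names the variant
    in all probands except one without listing ids, so ids beyond the nine
    printed for TAF1B are invented placeholders.

:func:`reference_cohort` embeds those three variants — plus common decoys —
as de novo events in a synthetic 16-trio cohort, the package's end-to-end
worked example.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import HET, AnnotationProfile, CohortTable, Variant
from .segregation import classify_genotypes
from .synthetic_cohort import SimulationConfig, generate_cohort

_DATA = resources.files("trioforge") / "data"


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_cohort_counts() -> pd.DataFrame:
    return _load("cpc_cohort_counts.tsv")


def load_assay_plex() -> pd.DataFrame:
    return _load("cpc_assay_plex.tsv")


def load_enrichment_reference() -> pd.DataFrame:
    return _load("cpc_enrichment.tsv")


def load_rare_variant_reference() -> pd.DataFrame:
    return _load("cpc_rare_variants.tsv")


def _proband_map(ref: pd.DataFrame, families) -> dict[str, str]:
    """Map the reference cohort's proband ids onto synthetic families."""
    ids = set()
    for plist in ref["probands"]:
        ids.update(str(plist).split(";"))
    ids.add("Z12")  # the one non-carrier proband of the MUC5B record
    ordered = sorted(ids)
    if len(ordered) > len(families):
        raise ValueError("more reference probands than synthetic families")
    return {zid: families[i].family_id for i, zid in enumerate(ordered)}


def reference_cohort(
    seed: int = 0,
    n_background: int = 1000,
    n_decoys: int = 50,
    depth_mean: float = 300.0,
):
    """Synthetic 16-trio cohort carrying the three reference candidates.

    The three published rare variants are planted as de novo heterozygous
    events in their carrier probands (annotations as published), alongside
    ``n_decoys`` common variants (population frequency >= 0.02) planted as
    de novo events — these segregate perfectly but must be removed by the
    frequency screen. Coverage is simulated at mean ``depth_mean`` so the
    family-depth gate (>= 250) is comfortably cleared and the example
    isolates the rarity/deleteriousness logic.

    Returns ``(cohort, expected)`` where ``expected`` maps each planted
    reference variant key to its row of the reference table.
    """
    cfg = SimulationConfig(
        n_families=16, n_quads=0, variants_per_exome=n_background,
        n_de_novo_per_proband=0, n_recessive_per_proband=0,
        depth_mean=depth_mean, seed=seed,
    )
    cohort, _truth = generate_cohort(cfg)
    rng = np.random.default_rng(seed + 101)
    ref = load_rare_variant_reference()
    zmap = _proband_map(ref, cohort.families)
    col = {s: j for j, s in enumerate(cohort.samples)}
    fam_by_id = {f.family_id: f for f in cohort.families}

    new_vars: list[Variant] = []
    new_profiles: list[AnnotationProfile] = []
    new_gt = []
    expected: dict[tuple, pd.Series] = {}

    def depth_row():
        k = cfg.depth_dispersion
        return rng.negative_binomial(k, k / (k + depth_mean), size=cohort.n_samples).astype(np.int32)

    new_dp = []
    for _, row in ref.iterrows():
        v = Variant(chrom=str(row["chrom"]), pos=int(row["pos"]), ref=row["ref"],
                    alt=row["alt"], gene=row["gene"], hgvs_g=row.get("hgvs_g"))
        prof = AnnotationProfile(
            af_pop=float(row["af_pop"]),
            cadd_phred=float(row["cadd_phred"]) if pd.notna(row["cadd_phred"]) else None,
            gerp=float(row["gerp"]) if pd.notna(row["gerp"]) else None,
            sift=row["sift"] if pd.notna(row.get("sift")) else None,
            polyphen=row["polyphen"] if pd.notna(row.get("polyphen")) else None,
            consequence=row["consequence"],
        )
        g = np.zeros(cohort.n_samples, dtype=np.int8)
        for zid in str(row["probands"]).split(";"):
            fam = fam_by_id[zmap[zid]]
            g[col[fam.proband]] = HET
        new_vars.append(v)
        new_profiles.append(prof)
        new_gt.append(g)
        new_dp.append(depth_row())
        expected[v.key] = row

    # common decoys: perfect de novo segregation, but common in the
    # population database, so the frequency screen must drop them
    probands = [f.proband for f in cohort.families]
    for d in range(n_decoys):
        chrom = str((d % 22) + 1)
        v = Variant(chrom=chrom, pos=90_000_000 + d * 97, ref="G", alt="A",
                    gene=f"DECOY{d:03d}")
        prof = AnnotationProfile(
            af_pop=float(rng.uniform(0.02, 0.5)),
            cadd_phred=float(rng.uniform(20, 40)),
            gerp=float(rng.uniform(2, 6)),
            sift="deleterious", polyphen="damaging",
            consequence="missense",
        )
        g = np.zeros(cohort.n_samples, dtype=np.int8)
        g[col[probands[d % len(probands)]]] = HET
        new_vars.append(v)
        new_profiles.append(prof)
        new_gt.append(g)
        new_dp.append(depth_row())

    merged = CohortTable(
        variants=cohort.variants + new_vars,
        samples=cohort.samples,
        gt=np.vstack([cohort.gt, np.vstack(new_gt)]),
        depth=np.vstack([cohort.depth, np.vstack(new_dp)]),
        profiles=cohort.profiles + new_profiles,
        families=cohort.families,
    )
    return merged, expected


def trio_enumeration() -> pd.DataFrame:
    """All 27 trio genotype combinations with their segregation labels."""
    cats = ["hom_ref", "het", "hom_alt"]
    code = {"hom_ref": 0, "het": 1, "hom_alt": 2}
    rows = []
    for pb in cats:
        for fa in cats:
            for mo in cats:
                label, _ = classify_genotypes(code[pb], code[fa], code[mo])
                rows.append({"proband": pb, "father": fa, "mother": mo, "label": label})
    return pd.DataFrame(rows)


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the packaged reference tables and derived fixtures to a directory."""
    from .variant_io import write_pedigree, write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("cpc_cohort_counts.tsv", "cpc_assay_plex.tsv",
                 "cpc_enrichment.tsv", "cpc_rare_variants.tsv"):
        dest = out / name
        dest.write_text((_DATA / name).read_text())
        written[name] = dest

    enum_path = out / "trio_enumeration.tsv"
    trio_enumeration().to_csv(enum_path, sep="\t", index=False)
    written["trio_enumeration.tsv"] = enum_path

    # minimal VCF/PED with just the three reference variants in 16 trios
    cohort, _ = reference_cohort(seed=0, n_background=0, n_decoys=0)
    written["rare_variants.vcf"] = write_vcf(cohort, out / "rare_variants.vcf")
    written["trios.ped"] = write_pedigree(cohort.families, out / "trios.ped")
    return written
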