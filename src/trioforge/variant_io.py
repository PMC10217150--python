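"""VCF / PED / sidecar-annotation ingestion and report writing.

The VCF contract: genotypes in ``GT`` (``DP`` optional), annotations carried
as INFO keys ``AF_POP, CADD, GERP, SIFT, POLYPHEN, MT, CSQ_CLASS, CLNSIG,
GENE`` (all optional; ``Number=A`` keys are split with the record).  A
sidecar TSV keyed by ``(chrom, pos, ref, alt)`` may override INFO values.

Multiallelic records are split into one :class:`~trioforge.model.Variant`
per alternate allele before anything downstream sees them; a genotype that
carries only *other* alternate alleles is recoded ``hom_ref`` with respect
to the allele under consideration, and ``./.`` stays ``missing``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    AnnotationProfile,
    CohortTable,
    Family,
    Variant,
    normalize_chrom,
)

INFO_KEYS = ("AF_POP", "CADD", "GERP", "SIFT", "POLYPHEN", "MT", "CSQ_CLASS", "CLNSIG", "GENE")

# RefSeq chromosome accessions for the GRCh38 assembly.
_HG38_ACCESSIONS = {
    "1": "NC_000001.11", "2": "NC_000002.12", "3": "NC_000003.12",
    "4": "NC_000004.12", "5": "NC_000005.10", "6": "NC_000006.12",
    "7": "NC_000007.14", "8": "NC_000008.11", "9": "NC_000009.12",
    "10": "NC_000010.11", "11": "NC_000011.10", "12": "NC_000012.12",
    "13": "NC_000013.11", "14": "NC_000014.9", "15": "NC_000015.10",
    "16": "NC_000016.10", "17": "NC_000017.11", "18": "NC_000018.10",
    "19": "NC_000019.10", "20": "NC_000020.11", "21": "NC_000021.9",
    "22": "NC_000022.11", "X": "NC_000023.11", "Y": "NC_000024.10",
}

_HGVS_SUB_RE = re.compile(
    r"^\s*NC_0*(\d+)\.\d+\s*:\s*g\.\s*(\d+)\s*([ACGT]+)\s*>\s*([ACGT]+)\s*$"
)


class VcfParseError(ValueError):
    pass


class PedigreeError(ValueError):
    pass


class HgvsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# HGVS genomic substitutions
# ---------------------------------------------------------------------------

def parse_hgvs_g(text: str) -> tuple[str, int, str, str]:
    """Parse a genomic HGVS substitution into a ``(chrom, pos, ref, alt)`` key.

    Only substitutions (``NC_...:g.<pos><ref> > <alt>``, spaces tolerated)
    are supported; deletions, insertions and other forms raise
    :class:`HgvsError`.
    """
    m = _HGVS_SUB_RE.match(text)
    if not m:
        raise HgvsError(f"unsupported HGVS form (substitutions only): {text!r}")
    acc_num, pos, ref, alt = m.groups()
    n = int(acc_num)
    if 1 <= n <= 22:
        chrom = str(n)
    elif n == 23:
        chrom = "X"
    elif n == 24:
        chrom = "Y"
    else:
        raise HgvsError(f"unknown chromosome accession NC_{acc_num}")
    return (chrom, int(pos), ref, alt)


def format_hgvs_g(variant: Variant) -> str:
    """Format a substitution as genomic HGVS against GRCh38 accessions."""
    acc = _HG38_ACCESSIONS[variant.chrom]
    return f"{acc}:g.{variant.pos}{variant.ref}>{variant.alt}"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_str(rec, key: str) -> Optional[str]:
    val = rec.INFO.get(key)
    if val is None:
        return None
    if isinstance(val, bytes):
        val = val.decode()
    if isinstance(val, (tuple, list, np.ndarray)):
        return ",".join("." if x is None else f"{x:.10g}" if isinstance(x, float) else str(x)
                        for x in val)
    if isinstance(val, float):
        return f"{val:.10g}"
    return str(val)


def _split_per_alt(raw: Optional[str], n_alts: int, alt_idx: int) -> Optional[str]:
    if raw is None:
        return None
    parts = str(raw).split(",")
    if len(parts) == n_alts:
        part = parts[alt_idx]
    else:
        part = parts[0]
    part = part.strip()
    return part if part not in ("", ".") else None


def _profile_from_info(rec, alt_idx: int, n_alts: int) -> AnnotationProfile:
    def get(key):
        return _split_per_alt(_info_str(rec, key), n_alts, alt_idx)

    af = get("AF_POP")
    cadd = get("CADD")
    gerp = get("GERP")
    return AnnotationProfile(
        af_pop=float(af) if af is not None else None,
        cadd_phred=float(cadd) if cadd is not None else None,
        gerp=float(gerp) if gerp is not None else None,
        sift=get("SIFT"),
        polyphen=get("POLYPHEN"),
        mutation_taster=get("MT"),
        consequence=get("CSQ_CLASS") or "other",
        clinvar=get("CLNSIG"),
    )


def read_vcf(path: str | Path, annot_path: Optional[str | Path] = None) -> CohortTable:
    """Read a multi-sample VCF into a :class:`CohortTable` fragment.

    Multiallelic records are split per alternate allele; chromosome labels
    are normalized (``chr11`` -> ``11``); absent annotations map to ``None``
    ("absent"). Sample order is preserved. Families are not populated here
    (see :func:`read_pedigree`).
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[Variant] = []
    profiles: list[Optional[AnnotationProfile]] = []
    gt_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    for lineno, rec in enumerate(vcf, start=1):
        try:
            chrom = normalize_chrom(rec.CHROM)
        except ValueError as exc:
            raise VcfParseError(f"{path}, record {lineno}: {exc}") from exc
        alts = rec.ALT
        gene = _info_str(rec, "GENE") or ""
        # allele-count matrix: genotypes as allele-index pairs
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        if rec.FORMAT and "DP" in rec.FORMAT:
            dp = np.asarray(rec.format("DP")).reshape(-1).astype(np.int64)
            dp = np.where(dp < 0, 0, dp)
        else:
            dp = np.zeros(len(samples), dtype=np.int64)
        for ai, alt in enumerate(alts):
            allele_num = ai + 1
            row = np.empty(len(samples), dtype=np.int8)
            for j, g in enumerate(gts):
                a = [x for x in g[:-1]]
                if any(x < 0 for x in a) or not a:
                    row[j] = MISSING
                else:
                    row[j] = sum(1 for x in a if x == allele_num)
            try:
                var = Variant(chrom=chrom, pos=rec.POS, ref=rec.REF, alt=alt, gene=gene)
            except ValueError as exc:
                raise VcfParseError(f"{path}, record {lineno}: {exc}") from exc
            variants.append(var)
            profiles.append(_profile_from_info(rec, ai, len(alts)))
            gt_rows.append(row)
            dp_rows.append(dp.astype(np.int32))
    n, m = len(variants), len(samples)
    gt = np.vstack(gt_rows) if gt_rows else np.zeros((0, m), dtype=np.int8)
    depth = np.vstack(dp_rows) if dp_rows else np.zeros((0, m), dtype=np.int32)
    table = CohortTable(variants=variants, samples=samples, gt=gt, depth=depth, profiles=profiles)
    if annot_path is not None:
        apply_sidecar_annotations(table, annot_path)
    return table


def write_vcf(table: CohortTable, path: str | Path) -> Path:
    """Write a cohort as VCF 4.2 text with the package's INFO contract."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF_POP,Number=A,Type=Float,Description="Population alternate allele frequency">',
        '##INFO=<ID=CADD,Number=A,Type=Float,Description="CADD Phred score">',
        '##INFO=<ID=GERP,Number=A,Type=Float,Description="GERP conservation score">',
        '##INFO=<ID=SIFT,Number=A,Type=String,Description="SIFT call">',
        '##INFO=<ID=POLYPHEN,Number=A,Type=String,Description="PolyPhen call">',
        '##INFO=<ID=MT,Number=A,Type=String,Description="MutationTaster call">',
        '##INFO=<ID=CSQ_CLASS,Number=A,Type=String,Description="Consequence class">',
        '##INFO=<ID=CLNSIG,Number=A,Type=String,Description="ClinVar significance">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for c in dict.fromkeys(v.chrom for v in table.variants):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    order = sorted(range(table.n_variants), key=lambda i: (
        table.variants[i].chrom.rjust(2), table.variants[i].pos, table.variants[i].alt))
    for i in order:
        v, p = table.variants[i], table.profiles[i]
        info = []
        if p is not None:
            if p.af_pop is not None:
                info.append(f"AF_POP={p.af_pop:.10g}")
            if p.cadd_phred is not None:
                info.append(f"CADD={p.cadd_phred:.10g}")
            if p.gerp is not None:
                info.append(f"GERP={p.gerp:.10g}")
            if p.sift is not None:
                info.append(f"SIFT={p.sift}")
            if p.polyphen is not None:
                info.append(f"POLYPHEN={p.polyphen}")
            if p.mutation_taster is not None:
                info.append(f"MT={p.mutation_taster}")
            info.append(f"CSQ_CLASS={p.consequence}")
            if p.clinvar is not None:
                info.append(f"CLNSIG={p.clinvar}")
        if v.gene:
            info.append(f"GENE={v.gene}")
        cols = [
            v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
            ";".join(info) if info else ".", "GT:DP",
        ]
        for j in range(table.n_samples):
            cols.append(f"{gt_str[int(table.gt[i, j])]}:{int(table.depth[i, j])}")
        lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Sidecar annotations
# ---------------------------------------------------------------------------

_SIDE_COLS = (
    "chrom", "pos", "ref", "alt", "af_pop", "cadd_phred", "gerp",
    "sift", "polyphen", "mutation_taster", "consequence", "clinvar",
)


def apply_sidecar_annotations(table: CohortTable, path: str | Path) -> None:
    """Overlay annotations from a TSV keyed by (chrom, pos, ref, alt).

    Sidecar values take precedence over anything read from INFO.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise VcfParseError(f"sidecar {path} lacks key columns {sorted(missing)}")
    for _, row in df.iterrows():
        key = (normalize_chrom(str(row["chrom"])), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        try:
            i = table.variant_index(key)
        except KeyError:
            continue

        def val(col, cast=None):
            if col not in row or pd.isna(row[col]):
                return None
            return cast(row[col]) if cast else row[col]

        table.profiles[i] = AnnotationProfile(
            af_pop=val("af_pop", float),
            cadd_phred=val("cadd_phred", float),
            gerp=val("gerp", float),
            sift=val("sift", str),
            polyphen=val("polyphen", str),
            mutation_taster=val("mutation_taster", str),
            consequence=val("consequence", str) or "other",
            clinvar=val("clinvar", str),
        )


# ---------------------------------------------------------------------------
# Pedigree (6-column PED)
# ---------------------------------------------------------------------------

_SEX = {"1": "male", "2": "female", "0": "unknown"}


def read_pedigree(path: str | Path) -> list[Family]:
    """Parse a whitespace-delimited 6-column PED file into families.

    The affected child (phenotype 2) becomes the proband; other children of
    the same parents with phenotype 1 become unaffected siblings. A family
    with an affected child missing either parent, or with two affected
    children, is rejected.
    """
    rows: list[tuple[str, str, str, str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        rows.append(tuple(parts[:6]))

    by_family: dict[str, list[tuple]] = {}
    for r in rows:
        by_family.setdefault(r[0], []).append(r)
    all_ids = {r[1] for r in rows}

    families: list[Family] = []
    for fid, members in by_family.items():
        affected = [r for r in members if r[5] == "2"]
        if len(affected) > 1:
            raise PedigreeError(f"family {fid}: multiple affected children are unsupported")
        if not affected:
            raise PedigreeError(f"family {fid}: no affected proband (phenotype 2)")
        prow = affected[0]
        _, proband, father, mother, sex, _ = prow
        if father in ("0", "") or mother in ("0", ""):
            raise PedigreeError(f"family {fid}: proband {proband} is missing a parent id (trio incomplete)")
        for pid, role in ((father, "father"), (mother, "mother")):
            if pid not in all_ids:
                raise PedigreeError(f"family {fid}: {role} id {pid!r} not present in pedigree")
        siblings = tuple(
            r[1] for r in members
            if r[1] not in (proband, father, mother) and r[2] == father and r[3] == mother
        )
        sexes = {r[1]: _SEX.get(r[4], "unknown") for r in members}
        families.append(Family(
            family_id=fid, proband=proband, father=father, mother=mother,
            siblings=siblings, proband_sex=_SEX.get(sex, "unknown"), sexes=sexes,
        ))
    return families


def write_pedigree(families: Sequence[Family], path: str | Path) -> Path:
    path = Path(path)
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    lines = []
    for fam in families:
        for sid in fam.members:
            if sid == fam.proband:
                father, mother, pheno = fam.father, fam.mother, "2"
            elif sid in fam.siblings:
                father, mother, pheno = fam.father, fam.mother, "1"
            else:
                father, mother, pheno = "0", "0", "1"
            sex = sex_code.get(fam.sexes.get(sid, "unknown"), "0")
            lines.append("\t".join([fam.family_id, sid, father, mother, sex, pheno]))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a summary table as TSV or JSON (records orientation).

    Machine outputs keep full numeric precision; display rounding is the
    reporting module's concern and never feeds back into computation.
    """
    path = Path(path)
    if fmt == "tsv":
        table.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=2, default=str) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r} (expected 'tsv' or 'json')")
    return path
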