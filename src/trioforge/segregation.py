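"""Mendelian segregation classification for proband-parent trios and quads.

Every (variant, family) pair with complete proband/father/mother genotypes
receives exactly one label:

``de_novo``
    proband het, both parents hom_ref, and every genotyped unaffected
    sibling hom_ref. A sibling that carries the alternate allele vetoes the
    de novo interpretation; a sibling with a missing call does not veto but
    is flagged in the call record.
``recessive_hom``
    proband hom_alt with both parents het (the classic recessive
    configuration) and no sibling hom_alt. Parent hom_alt configurations
    are Mendelian-consistent but are labelled inherited, not recessive,
    unless ``relaxed_recessive`` is set.
``inherited_paternal`` / ``inherited_maternal``
    proband het with exactly one parent carrying the alternate allele.
``inherited_ambiguous``
    proband het (or hom_alt outside the strict recessive configuration)
    with both parents carrying — single-site data cannot phase the origin.
``not_in_proband``
    proband hom_ref.
``mendelian_violation_other``
    transmission impossible under Mendel that is not the het de novo
    pattern (e.g. proband hom_alt with a hom_ref parent).
``unclassifiable_missing``
    proband or either parent has a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import HET, HOM_ALT, HOM_REF, MISSING, CohortTable, Family, GT_NAMES

LABELS = (
    "de_novo",
    "recessive_hom",
    "inherited_paternal",
    "inherited_maternal",
    "inherited_ambiguous",
    "not_in_proband",
    "mendelian_violation_other",
    "unclassifiable_missing",
)


@dataclass(frozen=True)
class SegregationCall:
    label: str
    family_id: str
    variant_key: tuple
    proband_gt: str
    father_gt: str
    mother_gt: str
    sibling_gts: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown segregation label {self.label!r}")


def classify_genotypes(
    proband: int,
    father: int,
    mother: int,
    siblings: Sequence[int] = (),
    relaxed_recessive: bool = False,
) -> tuple[str, tuple[str, ...]]:
    """Decision table over integer genotype codes; returns (label, flags).

    Codes: 0 hom_ref, 1 het, 2 hom_alt, -1 missing. Sibling missing calls
    never veto but add a ``sibling_missing`` flag.
    """
    if proband == MISSING or father == MISSING or mother == MISSING:
        return "unclassifiable_missing", ()
    flags: list[str] = []
    sibs = [s for s in siblings]
    if any(s == MISSING for s in sibs):
        flags.append("sibling_missing")
    called_sibs = [s for s in sibs if s != MISSING]

    if proband == HOM_REF:
        return "not_in_proband", tuple(flags)

    father_carries = father in (HET, HOM_ALT)
    mother_carries = mother in (HET, HOM_ALT)

    if proband == HET:
        if not father_carries and not mother_carries:
            if all(s == HOM_REF for s in called_sibs):
                return "de_novo", tuple(flags)
            return "mendelian_violation_other", tuple(flags + ["sibling_carries_alt"])
        if father == HOM_ALT and mother == HOM_ALT:
            # het child of two hom_alt parents is impossible
            return "mendelian_violation_other", tuple(flags)
        if father_carries and mother_carries:
            return "inherited_ambiguous", tuple(flags)
        if father_carries:
            return "inherited_paternal", tuple(flags)
        return "inherited_maternal", tuple(flags)

    # proband hom_alt
    if not father_carries or not mother_carries:
        return "mendelian_violation_other", tuple(flags)
    strict = father == HET and mother == HET
    if (strict or relaxed_recessive) and all(s != HOM_ALT for s in called_sibs):
        return "recessive_hom", tuple(flags)
    return "inherited_ambiguous", tuple(flags)


def classify_family(
    cohort: CohortTable,
    variant_idx: int,
    family: Family,
    relaxed_recessive: bool = False,
) -> SegregationCall:
    """Classify one (variant, family) pair from the cohort genotype matrix."""
    try:
        cols = [cohort.sample_index(s) for s in family.members]
    except KeyError as exc:
        raise ValueError(
            f"family {family.family_id} references a sample absent from the cohort: {exc}"
        ) from exc
    g = cohort.gt[variant_idx]
    pb, fa, mo = (int(g[c]) for c in cols[:3])
    sibs = [int(g[c]) for c in cols[3:]]
    label, flags = classify_genotypes(pb, fa, mo, sibs, relaxed_recessive=relaxed_recessive)
    return SegregationCall(
        label=label,
        family_id=family.family_id,
        variant_key=cohort.variants[variant_idx].key,
        proband_gt=GT_NAMES[pb],
        father_gt=GT_NAMES[fa],
        mother_gt=GT_NAMES[mo],
        sibling_gts=tuple(GT_NAMES[s] for s in sibs),
        flags=flags,
    )


@dataclass
class SegregationResult:
    calls: list[SegregationCall]
    tallies: pd.DataFrame  # rows: family_id, columns: label counts

    def calls_with_label(self, *labels: str) -> list[SegregationCall]:
        want = set(labels)
        return [c for c in self.calls if c.label in want]

    def pairs_with_label(self, *labels: str) -> set:
        want = set(labels)
        return {(c.variant_key, c.family_id) for c in self.calls if c.label in want}


def segregate_cohort(cohort: CohortTable, relaxed_recessive: bool = False) -> SegregationResult:
    """One SegregationCall per (variant, family), plus per-family tallies."""
    calls: list[SegregationCall] = []
    for fam in cohort.families:
        for i in range(cohort.n_variants):
            calls.append(classify_family(cohort, i, fam, relaxed_recessive=relaxed_recessive))
    if calls:
        df = pd.DataFrame({"family_id": [c.family_id for c in calls],
                           "label": [c.label for c in calls]})
        tallies = (
            df.groupby(["family_id", "label"]).size().unstack(fill_value=0)
            .reindex(columns=list(LABELS), fill_value=0)
        )
    else:
        tallies = pd.DataFrame(columns=list(LABELS))
    return SegregationResult(calls=calls, tallies=tallies)


def parental_origin_summary(
    calls: Iterable[SegregationCall],
    gene_of: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-gene (and per-family) counts of inherited-variant parental origin.

    ``gene_of`` maps variant keys to gene symbols; without it the variant
    key itself is the row key. Ambiguous-origin calls are tallied in their
    own column and never split across paternal/maternal.
    """
    rows = []
    for c in calls:
        if c.label not in ("inherited_paternal", "inherited_maternal", "inherited_ambiguous"):
            continue
        gene = (gene_of or {}).get(c.variant_key, "|".join(map(str, c.variant_key)))
        rows.append({"gene": gene, "family_id": c.family_id, "origin": c.label})
    if not rows:
        return pd.DataFrame(columns=["gene", "family_id", "paternal", "maternal", "ambiguous"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["gene", "family_id"])["origin"]
        .value_counts().unstack(fill_value=0)
        .reindex(columns=["inherited_paternal", "inherited_maternal", "inherited_ambiguous"],
                 fill_value=0)
        .rename(columns={
            "inherited_paternal": "paternal",
            "inherited_maternal": "maternal",
            "inherited_ambiguous": "ambiguous",
        })
        .reset_index()
    )
    out.columns.name = None
    return out


def calls_to_frame(calls: Iterable[SegregationCall]) -> pd.DataFrame:
    """Flatten calls into a table suitable for TSV export."""
    return pd.DataFrame([
        {
            "chrom": c.variant_key[0],
            "pos": c.variant_key[1],
            "ref": c.variant_key[2],
            "alt": c.variant_key[3],
            "family_id": c.family_id,
            "label": c.label,
            "proband_gt": c.proband_gt,
            "father_gt": c.father_gt,
            "mother_gt": c.mother_gt,
            "sibling_gts": ",".join(c.sibling_gts),
            "flags": ",".join(c.flags),
        }
        for c in calls
    ])
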