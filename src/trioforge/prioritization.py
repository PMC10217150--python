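"""Staged rare-variant filter cascade with multi-predictor consensus.

A candidate must (a) segregate as de novo or recessive-homozygous in at
least one family, (b) pass the family-mean site-depth gate in that family,
(c) be rare (strict tier, population frequency < 1%, with an "extreme"
tier at <= 5e-4 by default), and (d) be called deleterious by a k-of-m
predictor vote (SIFT, PolyPhen, MutationTaster, CADD, GERP) or be a
loss-of-function consequence, which short-circuits the vote.

The published filter text ("MAF < 0.01 and MAF <= 0.01%") is contradictory
as a single rule; it is implemented as a tiered cascade, with the extreme
tier's default (5e-4) wide enough to cover every frequency the reference
candidates print while the literal 1e-4 remains available by
configuration. A population frequency that is absent is treated as 0 —
never observed in the reference database is evidence of rarity — and
logged in the trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import LOF_CONSEQUENCES, AnnotationProfile, CohortTable, Family
from .segregation import SegregationResult

TIERS = ("fails_screen", "screened", "strict_rare", "extreme_rare")
_TIER_ORDER = {t: i for i, t in enumerate(TIERS)}


@dataclass
class FilterConfig:
    min_site_depth: float = 250.0
    maf_screen: float = 0.05
    maf_strict: float = 0.01
    maf_extreme: float = 5e-4
    consensus_min_votes: int = 2
    cadd_cutoff: float = 20.0
    gerp_cutoff: float = 2.0
    recurrence_min_probands: int = 2
    per_sample_min_depth: bool = False  # minimum over members instead of mean

    def validate(self) -> None:
        if not (self.maf_extreme <= self.maf_strict <= self.maf_screen):
            raise ValueError("thresholds must satisfy maf_extreme <= maf_strict <= maf_screen")
        if self.consensus_min_votes < 1:
            raise ValueError("consensus_min_votes must be >= 1")


@dataclass
class TrailEntry:
    stage: str
    decision: str        # "pass" | "fail"
    value: object
    threshold: object


@dataclass
class ProvenanceTrail:
    """Ordered record of every cascade stage applied to one variant."""

    variant_key: tuple
    entries: list[TrailEntry] = field(default_factory=list)

    def add(self, stage: str, passed: bool, value, threshold) -> bool:
        self.entries.append(TrailEntry(stage, "pass" if passed else "fail", value, threshold))
        return passed

    @property
    def all_pass(self) -> bool:
        return all(e.decision == "pass" for e in self.entries)

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(e.stage for e in self.entries)


def depth_filter(
    cohort: CohortTable,
    variant_idx: int,
    family: Family,
    config: FilterConfig,
) -> tuple[bool, TrailEntry]:
    """Family depth gate at one site: mean member depth >= threshold.

    With ``per_sample_min_depth`` the minimum member depth is gated
    instead. Boundary semantics are >= (a mean exactly at the threshold
    passes). Absent depth data fails with reason ``depth_missing``.
    """
    cols = [cohort.sample_index(s) for s in family.members]
    depths = cohort.depth[variant_idx, cols]
    if depths.size == 0:
        return False, TrailEntry("depth", "fail", "depth_missing", config.min_site_depth)
    stat = float(depths.min() if config.per_sample_min_depth else depths.mean())
    ok = stat >= config.min_site_depth
    return ok, TrailEntry("depth", "pass" if ok else "fail", stat, config.min_site_depth)


def maf_cascade(profile: Optional[AnnotationProfile], config: FilterConfig) -> tuple[str, list[TrailEntry]]:
    """Assign the rarity tier for a variant's population frequency."""
    af = None if profile is None else profile.af_pop
    entries: list[TrailEntry] = []
    if af is None:
        af = 0.0
        entries.append(TrailEntry("maf_absent_as_zero", "pass", None, None))
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"af_pop outside [0, 1]: {af}")
    if af <= config.maf_extreme:
        tier = "extreme_rare"
    elif af < config.maf_strict:
        tier = "strict_rare"
    elif af < config.maf_screen:
        tier = "screened"
    else:
        tier = "fails_screen"
    entries.append(TrailEntry("maf_screen", "pass" if af < config.maf_screen else "fail",
                              af, config.maf_screen))
    entries.append(TrailEntry("maf_strict", "pass" if _TIER_ORDER[tier] >= _TIER_ORDER["strict_rare"] else "fail",
                              af, config.maf_strict))
    entries.append(TrailEntry("maf_extreme", "pass" if tier == "extreme_rare" else "fail",
                              af, config.maf_extreme))
    return tier, entries


def predictor_consensus(
    profile: Optional[AnnotationProfile],
    config: FilterConfig,
) -> tuple[bool, dict]:
    """k-of-m deleteriousness vote with a loss-of-function short-circuit.

    Votes: SIFT deleterious, PolyPhen damaging, MutationTaster
    disease-causing, CADD Phred >= cutoff, GERP >= cutoff. Absent predictor
    calls abstain. A loss-of-function consequence (stop gained/lost,
    frameshift) is deleterious regardless of the vote.
    """
    if profile is None:
        return False, {"votes": 0, "detail": {}, "lof": False}
    detail = {
        "sift": profile.sift == "deleterious",
        "polyphen": profile.polyphen == "damaging",
        "mutation_taster": profile.mutation_taster == "disease_causing",
        "cadd": profile.cadd_phred is not None and profile.cadd_phred >= config.cadd_cutoff,
        "gerp": profile.gerp is not None and profile.gerp >= config.gerp_cutoff,
    }
    votes = sum(detail.values())
    lof = profile.consequence in LOF_CONSEQUENCES
    deleterious = lof or votes >= config.consensus_min_votes
    return deleterious, {"votes": votes, "detail": detail, "lof": lof}


def prioritize(
    cohort: CohortTable,
    segregation: SegregationResult,
    config: Optional[FilterConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """Reduce segregating variants to ranked rare deleterious candidates.

    Returns the candidate table and a dict of ProvenanceTrails keyed by
    variant key (one trail per variant that entered the cascade, i.e. every
    variant with at least one de novo / recessive-homozygous call).

    Ranking: extreme-rarity tier first, then number of carrier probands
    (descending), then CADD Phred (descending), ties broken by (chrom, pos).
    """
    config = config or FilterConfig()
    config.validate()
    fam_by_id = {f.family_id: f for f in cohort.families}

    seg_pairs: dict[tuple, list] = {}
    for call in segregation.calls_with_label("de_novo", "recessive_hom"):
        seg_pairs.setdefault(call.variant_key, []).append(call)

    trails: dict[tuple, ProvenanceTrail] = {}
    rows = []
    for key, calls in seg_pairs.items():
        i = cohort.variant_index(key)
        v, profile = cohort.variants[i], cohort.profiles[i]
        trail = ProvenanceTrail(variant_key=key)
        trails[key] = trail
        trail.add("segregation", True, sorted({c.label for c in calls}), None)

        depth_families = []
        best_entry = None
        for call in calls:
            ok, entry = depth_filter(cohort, i, fam_by_id[call.family_id], config)
            if ok:
                depth_families.append(call.family_id)
            if best_entry is None or (entry.decision == "pass" and best_entry.decision != "pass"):
                best_entry = entry
        trail.entries.append(TrailEntry("depth", "pass" if depth_families else "fail",
                                        best_entry.value if best_entry else "depth_missing",
                                        config.min_site_depth))

        tier, maf_entries = maf_cascade(profile, config)
        trail.entries.extend(e for e in maf_entries if e.stage in ("maf_screen", "maf_strict"))
        rare_enough = _TIER_ORDER[tier] >= _TIER_ORDER["strict_rare"]

        deleterious, votes = predictor_consensus(profile, config)
        trail.add("consensus", deleterious, votes["votes"], config.consensus_min_votes)

        if not (depth_families and rare_enough and deleterious):
            continue

        # carriers among probands (within-cohort recurrence)
        carrier_probands = [
            f.family_id for f in cohort.families
            if cohort.gt[i, cohort.sample_index(f.proband)] in (1, 2)
        ]
        rows.append({
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "tier": tier,
            "af_pop": profile.af_pop if profile else None,
            "cadd_phred": profile.cadd_phred if profile else None,
            "consequence": profile.consequence if profile else "other",
            "votes": votes["votes"],
            "lof": votes["lof"],
            "labels": ";".join(sorted({c.label for c in calls})),
            "families": ";".join(sorted(c.family_id for c in calls)),
            "n_probands": len(carrier_probands),
            "carrier_probands": ";".join(carrier_probands),
            "cohort_carrier_fraction": len(carrier_probands) / max(len(cohort.families), 1),
            "recurrent": len(carrier_probands) >= config.recurrence_min_probands,
        })

    candidates = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "gene", "tier", "af_pop", "cadd_phred",
        "consequence", "votes", "lof", "labels", "families", "n_probands",
        "carrier_probands", "cohort_carrier_fraction", "recurrent",
    ])
    if len(candidates):
        candidates["_tier_rank"] = candidates["tier"].map({"extreme_rare": 0, "strict_rare": 1})
        candidates["_cadd"] = candidates["cadd_phred"].fillna(-1.0)
        candidates = (
            candidates.sort_values(
                ["_tier_rank", "n_probands", "_cadd", "chrom", "pos"],
                ascending=[True, False, False, True, True],
            )
            .drop(columns=["_tier_rank", "_cadd"])
            .reset_index(drop=True)
        )
        candidates.insert(0, "rank", candidates.index + 1)
        # cascade soundness: no candidate may be common
        assert (candidates["af_pop"].fillna(0.0) < config.maf_strict).all()
    else:
        candidates.insert(0, "rank", pd.Series(dtype=int))
    return candidates, trails
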