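"""ACMG evidence assignment and 5-tier combination (computable subset).

Six of the guideline's 28 evidence codes can be derived from this
pipeline's inputs and are implemented here:

* ``PVS1`` — null variant (stop gained/lost, frameshift consequence).
* ``PS2``  — confirmed de novo (trio segregation with confirmed parentage).
* ``PM2``  — absent from / extremely rare in population databases.
* ``PP3``  — computational evidence of deleteriousness (predictor votes).
* ``BS1``  — allele frequency greater than expected for the disorder.
* ``BA1``  — stand-alone benign allele frequency (>= 5%).

The remaining codes need functional, case-control or multi-family
segregation evidence outside this pipeline's inputs and are deliberately
out of scope. Frequency thresholds are configurable; the defaults place
the PM2/BS1 boundary at 1e-4, a conventional choice for an ultra-rare
disorder. Combination follows the standard guideline table; conflicting
pathogenic and benign evidence resolves to VUS, except BA1 which is
stand-alone benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import LOF_CONSEQUENCES, AnnotationProfile

CRITERIA = ("PVS1", "PS2", "PM2", "PP3", "BS1", "BA1")
CLASSIFICATIONS = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")


@dataclass
class AcmgThresholds:
    pm2_af_max: float = 1e-4
    bs1_af_min: float = 1e-4
    ba1_af_min: float = 0.05
    pp3_min_votes: int = 2

    def validate(self) -> None:
        if not (self.pm2_af_max <= self.bs1_af_min <= self.ba1_af_min):
            raise ValueError("need pm2_af_max <= bs1_af_min <= ba1_af_min")


@dataclass
class AcmgAssignment:
    criteria: frozenset
    classification: str
    rationale: dict


def assign_criteria(
    profile: AnnotationProfile,
    segregation_label: Optional[str] = None,
    thresholds: Optional[AcmgThresholds] = None,
    predictor_votes: Optional[int] = None,
) -> tuple[frozenset, dict]:
    """Derive the evidence-code set for one variant.

    ``predictor_votes`` is the deleteriousness vote count from the
    prioritization consensus; if not supplied it is recomputed with that
    module's defaults. PM2 and BS1 are mutually exclusive by the threshold
    ordering; an absent population frequency counts as 0 (never observed).
    """
    th = thresholds or AcmgThresholds()
    th.validate()
    if predictor_votes is None:
        from .prioritization import FilterConfig, predictor_consensus
        predictor_votes = predictor_consensus(profile, FilterConfig())[1]["votes"]

    af = profile.af_pop if profile.af_pop is not None else 0.0
    criteria: set[str] = set()
    rationale: dict[str, str] = {}
    if profile.consequence in LOF_CONSEQUENCES:
        criteria.add("PVS1")
        rationale["PVS1"] = f"null variant ({profile.consequence})"
    if segregation_label == "de_novo":
        criteria.add("PS2")
        rationale["PS2"] = "trio-confirmed de novo"
    if af >= th.ba1_af_min:
        criteria.add("BA1")
        rationale["BA1"] = f"af_pop {af:g} >= {th.ba1_af_min:g}"
    elif af > th.bs1_af_min:
        criteria.add("BS1")
        rationale["BS1"] = f"af_pop {af:g} > {th.bs1_af_min:g}"
    elif af <= th.pm2_af_max:
        criteria.add("PM2")
        rationale["PM2"] = f"af_pop {af:g} <= {th.pm2_af_max:g}"
    if predictor_votes >= th.pp3_min_votes:
        criteria.add("PP3")
        rationale["PP3"] = f"{predictor_votes} deleteriousness votes"
    return frozenset(criteria), rationale


def classify(criteria: frozenset | set) -> str:
    """Combine evidence codes into the 5-tier classification.

    Implements the guideline combining table restricted to the six codes
    this engine can assign (PVS = PVS1, PS = PS2, PM = PM2, PP = PP3,
    BS = BS1, BA = BA1).
    """
    unknown = set(criteria) - set(CRITERIA)
    if unknown:
        raise ValueError(f"unknown ACMG criteria: {sorted(unknown)}")
    pvs = int("PVS1" in criteria)
    ps = int("PS2" in criteria)
    pm = int("PM2" in criteria)
    pp = int("PP3" in criteria)
    bs = int("BS1" in criteria)
    ba = int("BA1" in criteria)

    if ba:
        return "benign"

    pathogenic = (
        (pvs and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = bs >= 2
    likely_benign = False  # needs BS+BP or 2xBP; BP codes are out of scope

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign or bs >= 1
    if path_side and benign_side:
        return "vus"
    if pathogenic:
        return "pathogenic"
    if likely_pathogenic:
        return "likely_pathogenic"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "vus"


def assign_and_classify(
    profile: AnnotationProfile,
    segregation_label: Optional[str] = None,
    thresholds: Optional[AcmgThresholds] = None,
    predictor_votes: Optional[int] = None,
) -> AcmgAssignment:
    criteria, rationale = assign_criteria(profile, segregation_label, thresholds, predictor_votes)
    return AcmgAssignment(criteria=criteria, classification=classify(criteria), rationale=rationale)
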