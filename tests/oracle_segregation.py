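"""Independent brute-force oracle for trio/quad segregation labels.

This is a literal transcription of the Mendelian decision table as an
explicit 27-entry lookup, written separately from the package's
classifier so the two can be compared combination-by-combination. R/H/A
denote hom_ref / het / hom_alt.
"""

TRIO_TABLE = {
    # proband hom_ref: the variant is simply not in the proband
    ("R", "R", "R"): "not_in_proband",
    ("R", "R", "H"): "not_in_proband",
    ("R", "R", "A"): "not_in_proband",
    ("R", "H", "R"): "not_in_proband",
    ("R", "H", "H"): "not_in_proband",
    ("R", "H", "A"): "not_in_proband",
    ("R", "A", "R"): "not_in_proband",
    ("R", "A", "H"): "not_in_proband",
    ("R", "A", "A"): "not_in_proband",
    # proband het
    ("H", "R", "R"): "de_novo",
    ("H", "R", "H"): "inherited_maternal",
    ("H", "R", "A"): "inherited_maternal",
    ("H", "H", "R"): "inherited_paternal",
    ("H", "H", "H"): "inherited_ambiguous",
    ("H", "H", "A"): "inherited_ambiguous",
    ("H", "A", "R"): "inherited_paternal",
    ("H", "A", "H"): "inherited_ambiguous",
    ("H", "A", "A"): "mendelian_violation_other",  # two hom_alt parents cannot yield het
    # proband hom_alt
    ("A", "R", "R"): "mendelian_violation_other",
    ("A", "R", "H"): "mendelian_violation_other",
    ("A", "R", "A"): "mendelian_violation_other",
    ("A", "H", "R"): "mendelian_violation_other",
    ("A", "H", "H"): "recessive_hom",
    ("A", "H", "A"): "inherited_ambiguous",
    ("A", "A", "R"): "mendelian_violation_other",
    ("A", "A", "H"): "inherited_ambiguous",
    ("A", "A", "A"): "inherited_ambiguous",
}

CODE = {"R": 0, "H": 1, "A": 2, "M": -1}


def oracle_label(pb: str, fa: str, mo: str, siblings: tuple[str, ...] = ()) -> str:
    """Expected label, including missing-call and one-sibling handling.

    Missing proband/parent -> unclassifiable_missing. A called sibling
    carrying the alternate allele demotes de_novo to
    mendelian_violation_other; a hom_alt sibling demotes recessive_hom to
    inherited_ambiguous. Missing sibling calls are ignored here (they only
    flag, never veto).
    """
    if "M" in (pb, fa, mo):
        return "unclassifiable_missing"
    base = TRIO_TABLE[(pb, fa, mo)]
    called = [s for s in siblings if s != "M"]
    if base == "de_novo" and any(s in ("H", "A") for s in called):
        return "mendelian_violation_other"
    if base == "recessive_hom" and any(s == "A" for s in called):
        return "inherited_ambiguous"
    return base
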