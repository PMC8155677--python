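"""ACMG/AMP rule engine: published classification rows, the exhaustive
rule-table oracle, auto-assignment, and batch tallies."""

import itertools

import pytest

from popepi.acmg import (
    AutoAssignConfig,
    EvidenceProfile,
    Mode,
    UnknownCodeError,
    Verdict,
    auto_assign_data_criteria,
    classify_batch,
    combine_criteria,
)

# The seven published pathogenic/likely-pathogenic evidence strings.
TABLE1 = {
    "AP1S3:F4C": "PS3;PM1;PP3;BS4",
    "TNFAIP3:A125V": "PS3;PM1;PP3",
    "MVK:V377I": "PS4;PM3;PP1;PP5;BP4",
    "RAB27A:R82C": "PM1;PM2;PP3;PP5",
    "NOD2:N852S": "PS3;PM3;PP3",
    "NLRP12:R352C": "PS3;PM1;PP3;PP5",
    "NLRP12:R284X": "PVS1;PM1;PP5",
}


# ---------------------------------------------------------------------------
# combine_criteria on published rows


def test_stop_gain_row_is_pathogenic_by_very_strong_rule():
    c = combine_criteria(EvidenceProfile.from_string("PVS1;PM1;PP5"))
    assert c.verdict is Verdict.PATHOGENIC
    assert c.rule_label == "P(i)(c)"


def test_functional_plus_domain_plus_insilico_is_likely_pathogenic():
    c = combine_criteria(EvidenceProfile.from_string("PS3;PM1;PP3"))
    assert c.verdict is Verdict.LIKELY_PATHOGENIC
    assert c.rule_label == "LP(ii)"


def test_empty_profile_is_uncertain_with_no_rule():
    c = combine_criteria(EvidenceProfile(()))
    assert c.verdict is Verdict.UNCERTAIN
    assert c.rule_label == ""
    assert c.conflict is False


def test_two_moderate_two_supporting_is_likely_pathogenic_v():
    c = combine_criteria(EvidenceProfile.from_string("PM1;PM2;PP3;PP5"))
    assert c.verdict is Verdict.LIKELY_PATHOGENIC
    assert c.rule_label == "LP(v)"


def test_paper_mode_pathogenic_side_wins_conflicts():
    c = combine_criteria(
        EvidenceProfile.from_string("PS3;PM1;PP3;BS4"), mode=Mode.PAPER
    )
    assert c.verdict is Verdict.LIKELY_PATHOGENIC
    assert c.conflict is True


def test_strict_mode_conflicting_rules_give_uncertain():
    # benign-side rule needs >= 2 supporting or strong+supporting
    c = combine_criteria(
        EvidenceProfile.from_string("PS3;PM1;PP3;BS4;BP4"), mode=Mode.STRICT
    )
    assert c.verdict is Verdict.UNCERTAIN
    assert c.conflict is True


def test_unknown_code_rejected():
    with pytest.raises(UnknownCodeError):
        EvidenceProfile.from_string("PS9")


# ---------------------------------------------------------------------------
# Exhaustive tier-count oracle

_P_CODES = (["PVS1"], ["PS1", "PS2", "PS3", "PS4"],
            ["PM1", "PM2", "PM3", "PM4", "PM5", "PM6"],
            ["PP1", "PP2", "PP3", "PP4", "PP5"])
_B_CODES = (["BA1"], ["BS1", "BS2", "BS3", "BS4"],
            ["BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"])


def _profile_from_counts(v, s, m, p, a, bs, bp) -> EvidenceProfile:
    codes = (_P_CODES[0][:v] + _P_CODES[1][:s] + _P_CODES[2][:m] + _P_CODES[3][:p]
             + _B_CODES[0][:a] + _B_CODES[1][:bs] + _B_CODES[2][:bp])
    return EvidenceProfile(codes)


def _oracle_verdict(v, s, m, p, a, bs, bp, mode: Mode) -> Verdict:
    """Independent rule-by-rule transcription of the published combining
    table (coded separately from the engine's tier-count logic)."""
    pathogenic = (
        (v >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    likely = (
        (v == 1 and m == 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    benign = a >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_side = Verdict.PATHOGENIC if pathogenic else (
        Verdict.LIKELY_PATHOGENIC if likely else None)
    ben_side = Verdict.BENIGN if benign else (
        Verdict.LIKELY_BENIGN if likely_benign else None)
    if path_side and ben_side:
        return Verdict.UNCERTAIN if mode is Mode.STRICT else path_side
    return path_side or ben_side or Verdict.UNCERTAIN


def test_engine_matches_oracle_over_all_feasible_tier_vectors():
    """All 33,600 feasible (v,s,m,p,a,bs,bp) vectors, both modes."""
    space = itertools.product(
        range(2), range(5), range(7), range(6), range(2), range(5), range(8)
    )
    n = 0
    for v, s, m, p, a, bs, bp in space:
        profile = _profile_from_counts(v, s, m, p, a, bs, bp)
        for mode in (Mode.PAPER, Mode.STRICT):
            got = combine_criteria(profile, mode).verdict
            want = _oracle_verdict(v, s, m, p, a, bs, bp, mode)
            assert got is want, (v, s, m, p, a, bs, bp, mode, got, want)
        n += 1
    assert n == 33_600


def test_modes_differ_only_where_both_sides_fire():
    space = itertools.product(
        range(2), range(5), range(7), range(6), range(2), range(5), range(8)
    )
    for counts in space:
        profile = _profile_from_counts(*counts)
        paper = combine_criteria(profile, Mode.PAPER)
        strict = combine_criteria(profile, Mode.STRICT)
        if paper.verdict is not strict.verdict:
            assert strict.verdict is Verdict.UNCERTAIN
            assert paper.conflict and strict.conflict


def test_pathogenic_monotonicity_without_benign_codes():
    """Adding pathogenic evidence never weakens the verdict (STRICT mode,
    benign-free profiles)."""
    order = {Verdict.UNCERTAIN: 0, Verdict.LIKELY_PATHOGENIC: 1,
             Verdict.PATHOGENIC: 2}
    space = list(itertools.product(range(2), range(5), range(7), range(6)))
    for v, s, m, p in space:
        base = order[combine_criteria(
            _profile_from_counts(v, s, m, p, 0, 0, 0), Mode.STRICT).verdict]
        for dv, ds, dm, dp in ((1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)):
            v2, s2, m2, p2 = v + dv, s + ds, m + dm, p + dp
            if v2 > 1 or s2 > 4 or m2 > 6 or p2 > 5:
                continue
            bumped = order[combine_criteria(
                _profile_from_counts(v2, s2, m2, p2, 0, 0, 0), Mode.STRICT).verdict]
            assert bumped >= base, (v, s, m, p, (dv, ds, dm, dp))


def test_verdict_depends_only_on_tier_counts():
    a = combine_criteria(EvidenceProfile(("PS1", "PM2", "PM5")))
    b = combine_criteria(EvidenceProfile(("PS4", "PM1", "PM3")))
    assert a.verdict is b.verdict and a.rule_label == b.rule_label


# ---------------------------------------------------------------------------
# auto-assignment


def test_null_variant_absent_everywhere_gets_pvs1_and_pm2():
    prof = auto_assign_data_criteria(
        consequence="stop_gain", lof_gene=True, reference_afs={}
    )
    assert prof.codes == {"PVS1", "PM2"}


def test_common_missense_gets_stand_alone_benign():
    prof = auto_assign_data_criteria(
        consequence="missense", reference_afs={"nfe": 0.12, "afr": 0.001}
    )
    assert "BA1" in prof.codes and "BS1" in prof.codes
    assert "PM2" not in prof.codes


def test_rare_deleterious_missense_gets_pp3_and_pm2():
    prof = auto_assign_data_criteria(
        consequence="missense",
        insilico_calls=["deleterious", "deleterious", "deleterious"],
        reference_afs={"nfe": 5e-5, "afr": 5e-5},
    )
    assert prof.codes == {"PP3", "PM2"}


def test_consensus_threshold_respected():
    cfg = AutoAssignConfig()
    prof = auto_assign_data_criteria(
        insilico_calls=["deleterious", "benign", "unknown"], config=cfg
    )
    assert prof.codes == set()  # 1/2 informative on each side, below 2/3
    prof = auto_assign_data_criteria(
        insilico_calls=["benign", "benign", "deleterious"], config=cfg
    )
    assert prof.codes == {"BP4"}  # 2/3 benign reaches the consensus fraction
    prof = auto_assign_data_criteria(insilico_calls=["benign", "benign"])
    assert prof.codes == {"BP4"}


def test_malformed_af_rejected():
    with pytest.raises(ValueError):
        auto_assign_data_criteria(reference_afs={"nfe": 1.5})


# ---------------------------------------------------------------------------
# batch classification of the published rows


def test_published_rows_all_pathogenic_or_likely_pathogenic():
    profiles = [EvidenceProfile.from_string(s) for s in TABLE1.values()]
    result = classify_batch(profiles, Mode.PAPER)
    verdicts = [c.verdict for c in result.classifications]
    assert all(
        v in (Verdict.PATHOGENIC, Verdict.LIKELY_PATHOGENIC) for v in verdicts
    )
    assert result.tally[Verdict.PATHOGENIC] == 1
    assert result.tally[Verdict.LIKELY_PATHOGENIC] == 6


def test_batch_tally_is_sum_of_individual_verdicts():
    import random

    rng = random.Random(5)
    all_codes = [c for tier in (_P_CODES + _B_CODES) for c in tier]
    profiles = [
        EvidenceProfile(rng.sample(all_codes, rng.randrange(0, 6)))
        for _ in range(100)
    ]
    result = classify_batch(profiles)
    individual = [combine_criteria(p).verdict for p in profiles]
    assert sum(result.tally.values()) == 100
    for verdict in Verdict:
        assert result.tally[verdict] == individual.count(verdict)
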