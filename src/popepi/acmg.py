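"""ACMG/AMP evidence-code engine.

Implements the 2015 ACMG/AMP framework for sequence-variant interpretation:
28 evidence codes (PVS1; PS1-4; PM1-6; PP1-5 on the pathogenic side; BA1;
BS1-4; BP1-7 on the benign side), each carrying a fixed strength tier, and
the published combining rules that map a set of codes to one of five
verdicts: Pathogenic, Likely pathogenic, Uncertain significance, Likely
benign, Benign.

Two conflict-handling modes are provided. In ``STRICT`` mode a profile where
both a pathogenic-side and a benign-side combining rule fire is Uncertain
(the conservative published reading). In ``PAPER`` mode the pathogenic-side
verdict wins and the conflict is flagged — the behaviour needed to reproduce
published classification tables where variants carrying e.g. BS4 or BP4
alongside strong pathogenic evidence are still called likely pathogenic.

Only the data-driven criteria (PVS1, PM2, BA1, BS1, PP3, BP4) can be
auto-assigned from annotations; the literature-tier codes must come from a
curated evidence table.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

# code -> (side, tier)
_PATHOGENIC_TIERS: dict[str, str] = {}
_BENIGN_TIERS: dict[str, str] = {}
for _c in ["PVS1"]:
    _PATHOGENIC_TIERS[_c] = "very_strong"
for _i in range(1, 5):
    _PATHOGENIC_TIERS[f"PS{_i}"] = "strong"
for _i in range(1, 7):
    _PATHOGENIC_TIERS[f"PM{_i}"] = "moderate"
for _i in range(1, 6):
    _PATHOGENIC_TIERS[f"PP{_i}"] = "supporting"
_BENIGN_TIERS["BA1"] = "stand_alone"
for _i in range(1, 5):
    _BENIGN_TIERS[f"BS{_i}"] = "strong"
for _i in range(1, 8):
    _BENIGN_TIERS[f"BP{_i}"] = "supporting"

ALL_CODES: frozenset[str] = frozenset(_PATHOGENIC_TIERS) | frozenset(_BENIGN_TIERS)


class Mode(str, enum.Enum):
    """Conflict-handling mode for the combining rules."""

    PAPER = "PAPER"
    STRICT = "STRICT"


class Verdict(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    UNCERTAIN = "UNCERTAIN"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"


class UnknownCodeError(ValueError):
    """An evidence code outside the 28-code ACMG/AMP vocabulary."""


@dataclass(frozen=True)
class EvidenceProfile:
    """A set of ACMG/AMP evidence codes attached to one variant."""

    codes: frozenset[str]

    def __init__(self, codes: Iterable[str]):
        codes = frozenset(c.strip().upper() for c in codes if str(c).strip())
        unknown = codes - ALL_CODES
        if unknown:
            raise UnknownCodeError(f"unknown ACMG code(s): {sorted(unknown)}")
        object.__setattr__(self, "codes", codes)

    @classmethod
    def from_string(cls, s: str, sep: str = ";") -> "EvidenceProfile":
        """Parse e.g. ``"PS3;PM1;PP3"`` (commas also accepted)."""
        return cls(s.replace(",", sep).split(sep)) if s.strip() else cls(())

    def tier_counts(self) -> tuple[int, int, int, int, int, int, int]:
        """(v, s, m, p, a, bs, bp): counts per strength tier."""
        v = s = m = p = a = bs = bp = 0
        for c in self.codes:
            tier = _PATHOGENIC_TIERS.get(c)
            if tier == "very_strong":
                v += 1
            elif tier == "strong":
                s += 1
            elif tier == "moderate":
                m += 1
            elif tier == "supporting":
                p += 1
            else:
                tier = _BENIGN_TIERS[c]
                if tier == "stand_alone":
                    a += 1
                elif tier == "strong":
                    bs += 1
                else:
                    bp += 1
        return v, s, m, p, a, bs, bp

    @property
    def has_pathogenic_codes(self) -> bool:
        return any(c in _PATHOGENIC_TIERS for c in self.codes)

    @property
    def has_benign_codes(self) -> bool:
        return any(c in _BENIGN_TIERS for c in self.codes)


@dataclass(frozen=True)
class Classification:
    """Verdict plus the combining rule that produced it.

    ``rule_label`` names the satisfied rule in the framework's Roman/letter
    notation (e.g. ``"P(i)(c)"``, ``"LP(ii)"``); it is empty only for an
    Uncertain verdict where no rule fired at all. ``conflict`` is true when
    evidence or rules from both sides are present.
    """

    verdict: Verdict
    rule_label: str = ""
    conflict: bool = False


def _pathogenic_rule(v: int, s: int, m: int, p: int) -> str | None:
    """First satisfied Pathogenic combining rule, or None."""
    if v >= 1:
        if s >= 1:
            return "P(i)(a)"
        if m >= 2:
            return "P(i)(b)"
        if m >= 1 and p >= 1:
            return "P(i)(c)"
        if p >= 2:
            return "P(i)(d)"
    if s >= 2:
        return "P(ii)"
    if s == 1:
        if m >= 3:
            return "P(iii)(a)"
        if m == 2 and p >= 2:
            return "P(iii)(b)"
        if m == 1 and p >= 4:
            return "P(iii)(c)"
    return None


def _likely_pathogenic_rule(v: int, s: int, m: int, p: int) -> str | None:
    """First satisfied Likely-pathogenic combining rule, or None."""
    if v == 1 and m == 1:
        return "LP(i)"
    if s == 1 and 1 <= m <= 2:
        return "LP(ii)"
    if s == 1 and p >= 2:
        return "LP(iii)"
    if m >= 3:
        return "LP(iv)"
    if m == 2 and p >= 2:
        return "LP(v)"
    if m == 1 and p >= 4:
        return "LP(vi)"
    return None


def _benign_rule(a: int, bs: int, bp: int) -> str | None:
    if a >= 1:
        return "B(i)"
    if bs >= 2:
        return "B(ii)"
    return None


def _likely_benign_rule(bs: int, bp: int) -> str | None:
    if bs == 1 and bp >= 1:
        return "LB(i)"
    if bp >= 2:
        return "LB(ii)"
    return None


def combine_criteria(
    profile: EvidenceProfile, mode: Mode | str = Mode.PAPER
) -> Classification:
    """Apply the ACMG/AMP combining rules to an evidence profile.

    The verdict depends only on per-tier code counts; permuting codes within
    a tier never changes the outcome. See module docstring for the two
    conflict modes.
    """
    mode = Mode(mode)
    v, s, m, p, a, bs, bp = profile.tier_counts()

    path_label = _pathogenic_rule(v, s, m, p)
    path_verdict = Verdict.PATHOGENIC if path_label else None
    if path_label is None:
        path_label = _likely_pathogenic_rule(v, s, m, p)
        path_verdict = Verdict.LIKELY_PATHOGENIC if path_label else None

    ben_label = _benign_rule(a, bs, bp)
    ben_verdict = Verdict.BENIGN if ben_label else None
    if ben_label is None:
        ben_label = _likely_benign_rule(bs, bp)
        ben_verdict = Verdict.LIKELY_BENIGN if ben_label else None

    both_fire = path_verdict is not None and ben_verdict is not None
    conflict = both_fire or (
        (path_verdict is not None and profile.has_benign_codes)
        or (ben_verdict is not None and profile.has_pathogenic_codes)
    )

    if both_fire:
        if mode is Mode.STRICT:
            return Classification(
                Verdict.UNCERTAIN, f"CONFLICT[{path_label}|{ben_label}]", True
            )
        return Classification(path_verdict, path_label, True)
    if path_verdict is not None:
        return Classification(path_verdict, path_label, conflict)
    if ben_verdict is not None:
        return Classification(ben_verdict, ben_label, conflict)
    return Classification(Verdict.UNCERTAIN, "", conflict)


# ---------------------------------------------------------------------------
# Data-driven auto-assignment


@dataclass(frozen=True)
class AutoAssignConfig:
    """Thresholds for the frequency/consequence-driven criteria.

    rare_threshold
        PM2 fires when AF is below this in every reference population (or the
        variant is absent everywhere). Default 1e-4.
    ba1_threshold
        BA1 (stand-alone benign) fires when AF exceeds this in any general
        reference population. Default 0.05.
    bs1_threshold
        BS1 fires above this disorder-specific maximum credible AF. Default 0.01.
    deleterious_consensus
        PP3 (resp. BP4) fires when at least this fraction of the provided
        in-silico calls are deleterious (resp. benign). Default 2/3.
    """

    rare_threshold: float = 1e-4
    ba1_threshold: float = 0.05
    bs1_threshold: float = 0.01
    deleterious_consensus: float = 2.0 / 3.0


NULL_CONSEQUENCES = frozenset(
    {"stop_gain", "stopgain", "frameshift", "canonical_splice", "splice_donor",
     "splice_acceptor", "start_loss", "startloss"}
)


def auto_assign_data_criteria(
    consequence: str | None = None,
    lof_gene: bool = False,
    insilico_calls: Sequence[str] | None = None,
    reference_afs: Mapping[str, float] | None = None,
    config: AutoAssignConfig | None = None,
) -> EvidenceProfile:
    """Assign the purely data-driven criteria from variant annotations.

    Parameters
    ----------
    consequence
        Functional consequence class (e.g. "missense", "stop_gain"); PVS1
        requires a null consequence *and* ``lof_gene=True``.
    lof_gene
        Whether loss of function is an established disease mechanism for
        the gene.
    insilico_calls
        Per-tool deleteriousness calls, each "deleterious" or "benign"
        (other strings are ignored as uninformative).
    reference_afs
        Allele frequency per reference population. Absent (empty mapping or
        None) counts as "not observed", which satisfies PM2. Missing fields
        skip their criteria entirely.

    Returns a partial :class:`EvidenceProfile`; literature-tier codes are
    never auto-assigned.
    """
    cfg = config or AutoAssignConfig()
    codes: set[str] = set()

    if reference_afs is not None:
        for pop, af in reference_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"malformed AF {af} for population {pop!r}")
        afs = list(reference_afs.values())
        if all(af < cfg.rare_threshold for af in afs):  # vacuously true if absent
            codes.add("PM2")
        if any(af > cfg.ba1_threshold for af in afs):
            codes.add("BA1")
        if any(af > cfg.bs1_threshold for af in afs):
            codes.add("BS1")

    if consequence is not None:
        norm = consequence.strip().lower().replace("-", "_").replace(" ", "_")
        if norm in NULL_CONSEQUENCES and lof_gene:
            codes.add("PVS1")

    if insilico_calls:
        calls = [c.strip().lower() for c in insilico_calls]
        informative = [c for c in calls if c in ("deleterious", "benign")]
        if informative:
            n = len(informative)
            if sum(c == "deleterious" for c in informative) / n >= cfg.deleterious_consensus:
                codes.add("PP3")
            if sum(c == "benign" for c in informative) / n >= cfg.deleterious_consensus:
                codes.add("BP4")

    return EvidenceProfile(codes)


# ---------------------------------------------------------------------------
# Batch classification


@dataclass
class BatchResult:
    classifications: list[Classification]
    tally: Counter = field(default_factory=Counter)


def classify_batch(
    profiles: Sequence[EvidenceProfile], mode: Mode | str = Mode.PAPER
) -> BatchResult:
    """Element-wise :func:`combine_criteria` plus a per-verdict tally."""
    classifications = [combine_criteria(p, mode) for p in profiles]
    tally = Counter(c.verdict for c in classifications)
    return BatchResult(classifications=classifications, tally=tally)
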