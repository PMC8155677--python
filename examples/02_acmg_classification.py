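"""ACMG/AMP classification of curated evidence profiles.

Runs the combining-rule engine over seven evidence-code strings typical of
a rare autoinflammatory-disease reclassification (functional data PS3,
hotspot PM1, in-silico PP3, etc.) and prints the five-class verdict, the
rule satisfied, and whether benign-side evidence conflicted.
"""

from popepi import EvidenceProfile, Mode, combine_criteria

VARIANTS = [
    ("AP1S3 p.F4C", "PS3;PM1;PP3;BS4"),
    ("TNFAIP3 p.A125V", "PS3;PM1;PP3"),
    ("MVK p.V377I", "PS4;PM3;PP1;PP5;BP4"),
    ("RAB27A p.R82C", "PM1;PM2;PP3;PP5"),
    ("NOD2 p.N852S", "PS3;PM3;PP3"),
    ("NLRP12 p.R352C", "PS3;PM1;PP3;PP5"),
    ("NLRP12 p.R284X", "PVS1;PM1;PP5"),
]

print(f"{'variant':18} {'criteria':24} {'verdict':18} {'rule':10} conflict")
for name, codes in VARIANTS:
    c = combine_criteria(EvidenceProfile.from_string(codes), Mode.PAPER)
    print(f"{name:18} {codes:24} {c.verdict.value:18} {c.rule_label:10} "
          f"{c.conflict}")

# PAPER mode lets the pathogenic side win when benign evidence (BS4, BP4)
# co-occurs, flagging the conflict; STRICT mode would call those profiles
# UNCERTAIN instead:
c = combine_criteria(EvidenceProfile.from_string("PS3;PM1;PP3;BS4;BP4"),
                     Mode.STRICT)
print(f"\nSTRICT mode on PS3;PM1;PP3;BS4;BP4 -> {c.verdict.value} "
      f"({c.rule_label})")
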