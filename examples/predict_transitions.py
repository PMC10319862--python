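"""Predict the diagnostic OzID ions for a handful of fatty acids.

Each carbon-carbon double bond of an ozonolysed, AMPP-derivatized fatty
acid yields an aldehyde ion and a Criegee ion (one oxygen heavier); their
m/z values identify the bond position directly.
"""

from ozfad import builtin_agents, ozid_transitions, parse_shorthand, precursor_mz, systematic_name

agent = builtin_agents()["AMPP"]

for shorthand in ("FA 18:1n-9 cis", "FA 20:3n-9,12,15 cis", "FA 22:6n-3,6,9,12,15,18 cis"):
    fa = parse_shorthand(shorthand)
    print(f"{shorthand}  ({systematic_name(fa)})")
    print(f"  precursor m/z {precursor_mz(fa, agent):.4f}")
    for t in ozid_transitions(fa, agent).transitions:
        print(f"  n-{t.position:<2d} aldehyde {t.aldehyde_mz:9.4f}   criegee {t.criegee_mz:9.4f}")
    print()

# The 449.35 / 339.21 / 355.20 trio for oleic acid is the classic fingerprint:
# finding the 339/355 pair co-eluting with the 449 precursor localizes the
# double bond nine carbons from the methyl terminus.
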