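"""Interrogate the packaged sequential-electron-transfer energy ladder.

Loads the TTAG AG-anti excited-state diagram (energies in eV above the
ground-state minimum), prints the cascade gaps and classifies which decay
channels are thermally accessible.
"""

from cpdrepair.set_ladder import (
    classify_channel,
    gap,
    load_packaged_ladder,
    validate_ladder,
)

ladder = load_packaged_ladder("ttag_ag_anti")
print(f"{ladder.system_label} (reference: {ladder.reference})")
for p in ladder.points:
    print(f"  {p.name:9s} {p.kind:7s} {p.energy_eV:5.2f} eV  [{p.provenance}]")

print()
print(f"G*  -> A-G+   driving force: {gap(ladder, 'G*', 'A-G+'):+.2f} eV")
print(f"A-G+ -> TT-AG+ driving force: {gap(ladder, 'A-G+', 'TT-AG+'):+.2f} eV")
print(f"G*  -> MECP_G  barrier {gap(ladder, 'G*', 'MECP_G'):+.2f} eV -> "
      f"{classify_channel(ladder, 'G*', 'MECP_G')}")
print(f"TT-AG+ -> MECP_CPD barrier {gap(ladder, 'TT-AG+', 'MECP_CPD'):+.2f} eV -> "
      f"{classify_channel(ladder, 'TT-AG+', 'MECP_CPD')}")

failures = [c for c in validate_ladder(ladder) if not c.passed]
print(f"validation: {'all checks passed' if not failures else failures}")
# Hindered direct relaxation of G* plus a barrierless final crossing is what
# channels the excitation down the electron-transfer cascade to CPD splitting.
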