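"""The six-molecule worked example: Hasse diagram and equivalence classes.

Twelve patterns over molecules M1..M6 with known structure: prints the
cover edges, then the GEC/DEC/SEC condensation, showing how patterns
with identical supports collapse.
"""

from padmine import build_network, compute_gec, compute_sec
from padmine.synth import worked_example_fixture

index, _, expected = worked_example_fixture()
net = build_network(index)
print(f"{len(index)} pharmacophores, {len(net.edges)} cover edges "
      f"(matches the drawing: {net.edges == set(expected.edges)})")
print("\nedges (parent -> child):")
for u, v in sorted(net.edges):
    print(f"  {u}  ->  {v}")

print("\nAN covers both of its extensions:")
print(" ", sorted(net.children("|A|N| |2|")))

gecs = compute_gec(net)
secs = compute_sec(net)
print(f"\n{len(gecs)} GECs (same support) refine into {len(secs)} SECs "
      f"(same support AND connected):")
for ec in secs:
    print(f"  SEC rep {ec.representative:<28} members={len(ec.members)} "
          f"support={sorted(ec.support)}")
# The three order-1 patterns share one support but are not connected to
# each other, so one GEC splits into three SECs; the {M2} class stays a
# single SEC because the order-4 pattern connects its three parents.
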