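"""Classify GGDEF / EAL / PilZ domain sequences as ACTIVE or DEGENERATE.

Builds a minimal diguanylate-cyclase active-site motif instance, breaks
it with a single substitution, and shows how the classifier reports
which essential residue failed and whether the allosteric I-site
(RxxD five residues upstream of the A-site block) is present.
"""

from cdgscan import classify_ggdef, classify_pilz, serialize_pattern, GGDEF_PATTERN

# A minimal GGDEF active-site motif: D x(7) N x(8) D x(21) R x [GSA] G [DE] E F
active = "D" + "A" * 7 + "N" + "A" * 8 + "D" + "A" * 21 + "R" + "A" + "GGDEF"

print("GGDEF pattern:", serialize_pattern(GGDEF_PATTERN))
call = classify_ggdef(active)
print(f"minimal instance ({len(active)} aa): {call.status}, "
      f"I-site: {call.i_site_present}")

# Substitute the terminal F of the A-site block -> degenerate domain
broken = active[:-1] + "A"
call = classify_ggdef(broken)
print(f"terminal F -> A: {call.status}, failed essentials "
      f"(rank, observed): {call.mismatched_essentials}")

# Plant an RxxD so its D sits exactly 5 residues before the A-site block
with_i_site = list(active)
a_site = 42  # 1-based position of the [GSA] residue in this instance
with_i_site[a_site - 5 - 1] = "D"
with_i_site[a_site - 8 - 1] = "R"
call = classify_ggdef("".join(with_i_site))
print(f"with planted RxxD: {call.status}, I-site: {call.i_site_present}")

# PilZ receptor motif with a ranged spacer (20-30 residues)
pilz = "R" + "AAA" + "R" + 25 * "A" + "D" + "A" + "S" + "AA" + "G"
print(f"PilZ, 25-residue spacer: {classify_pilz(pilz).status}")

# Expected output: the minimal instance is ACTIVE without an I-site;
# the single substitution flips it to DEGENERATE naming essential 8
# (the terminal F); the planted RxxD turns the I-site flag on.
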