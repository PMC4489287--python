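"""Accessibility and conservation verdicts for a single seed-match site.

Shows the inclusive 20% accessibility threshold, the loose vs strict
window placement, and conservation through a gapped ortholog alignment.
"""

from paccmit import (
    AccessibilityPolicy,
    OrthologAlignment,
    SeedMatchSite,
    is_accessible,
    is_conserved,
    unpaired_window_fraction,
)
from paccmit.fixtures import make_ensemble

# 10 structures; the 4-mer at the site's 3' end (positions 14..17) is
# unpaired in exactly 2 of them (20%)
ensemble = make_ensemble("TX1", 40, 10, {14: 0.2})
site = SeedMatchSite("TX1", 11, 7)

f = unpaired_window_fraction(ensemble, 14, 4)
print(f"unpaired fraction of the 3'-end 4-mer: {f:.2f}")
for mode in ("loose", "strict"):
    verdict = is_accessible(site, ensemble, AccessibilityPolicy(mode=mode))
    print(f"accessible ({mode:6s}, threshold >= 0.20): {verdict}")

alignment = OrthologAlignment(
    "TX1",
    (
        ("TX1",   "ACGT-TACGTTTCCTGACGTACGTACGTACGTACGTACGTA"),
        ("mouse", "ACGTATACGTTTCCTGACGTACGTACGTACGTACGTACGTA"),
        ("rat",   "ACGTATACGTTTCATGACGTACGTACGTACGTACGTACGTA"),
    ),
)
for k in (1, 2):
    print(f"conserved in >= {k} other species: {is_conserved(site, alignment, k)}")
print()
print("Exactly 20% unpaired passes (the threshold is inclusive).  The rat row")
print("carries a substitution inside the site, so requiring both species fails")
print("while requiring one succeeds.")
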