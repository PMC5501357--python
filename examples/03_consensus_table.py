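"""Cross-donor consensus calls and report-style display rows.

Shows the >=3-of-5 counting rule on hand-built per-donor evidence,
including the no-veto behaviour: donors disagreeing with the majority
direction do not cancel a call.
"""

from lfqpair import PairDifference, consensus_call
from lfqpair.differential import MODE_BOTH, MODE_CTL_ONLY, MODE_IFN_ONLY

DONORS = ["d1", "d2", "d3", "d4", "d5"]


def both(donor, z):
    return PairDifference("PROT", donor, MODE_BOTH, D=z * 0.8, Z=z,
                          ifn_log2=12.0 + z * 0.8, ctl_log2=12.0)


def only(donor, mode):
    sign = 1 if mode == MODE_IFN_ONLY else -1
    return PairDifference("PROT", donor, mode, D=sign * 12.0, Z=sign * 15.0)


cases = {
    "clear induction (3 donors over 2 SD)":
        [both("d1", 2.5), both("d2", 2.1), both("d3", 3.0), both("d4", -0.3), both("d5", 1.0)],
    "presence/absence with a dissenting donor (no veto)":
        [only("d1", MODE_IFN_ONLY), only("d2", MODE_IFN_ONLY), only("d3", MODE_IFN_ONLY),
         both("d4", 0.0), only("d5", MODE_CTL_ONLY)],
    "not consistent enough (2 of 5)":
        [both("d1", 2.5), both("d2", 2.1), both("d3", 0.4), both("d4", -0.3), both("d5", 1.0)],
}

for label, diffs in cases.items():
    call = consensus_call(diffs, DONORS)
    row = "  ".join(f"{tok:>4}" for tok in call.per_donor_display)
    print(f"{label}\n  direction={call.direction:9}  qualifying donors={call.n_qualifying}")
    print(f"  display row: {row}\n")

print("Display tokens follow the reporting convention: a fold value when the "
      "protein was seen in both conditions, IFN/CTL when it was detected only "
      "in the treated/untreated sample, and '–' when absent from that donor.")
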