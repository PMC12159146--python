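"""Hand-constructed allele-specific segment profiles with manually
enumerated TAI / HRD-LOH / LST counts.

Every case was counted by hand against the definitions: TAI = merged
allelic-imbalance runs touching a chromosome end without intersecting the
centromere (no minimum size); HRD-LOH = merged copyB=0, copyA>=1 runs
>= 15 Mb not spanning a whole chromosome; LST = arm-internal breakpoints
between runs both >= 10 Mb after removing segments < 3 Mb and re-merging
equal copy states.  Note that a breakpoint bordering a counted LOH or AI
run also counts toward LST when both flanks are large enough.

Genome: c1 = 100 Mb, centromere [45, 50) Mb; c2 = 60 Mb, centromere
[25, 27) Mb.  Coordinates in the cases below are megabases.
"""

import pandas as pd

from diastab.hrd import AllelicSegmentProfile, GenomeModel

MB = 1_000_000

BATTERY_GENOME = GenomeModel({
    "c1": (100 * MB, 45 * MB, 50 * MB),
    "c2": (60 * MB, 25 * MB, 27 * MB),
})


def _profile(name: str, segs: list[tuple]) -> AllelicSegmentProfile:
    rows = [
        {"chrom": c, "start": int(s * MB), "end": int(e * MB),
         "copy_a": ca, "copy_b": cb}
        for (c, s, e, ca, cb) in segs
    ]
    return AllelicSegmentProfile(sample_id=name, segments=pd.DataFrame(rows))


def _c2_balanced():
    return [("c2", 0, 60, 1, 1)]


#: (profile, expected_tai, expected_loh, expected_lst)
SCAR_CASES: list[tuple[AllelicSegmentProfile, int, int, int]] = [
    # 1. fully balanced genome
    (_profile("balanced", [("c1", 0, 100, 1, 1)] + _c2_balanced()), 0, 0, 0),
    # 2. telomeric AI on the p-arm; its distal breakpoint (30 Mb | 15 Mb
    #    flanks) is also one LST
    (_profile("tai_p", [("c1", 0, 30, 2, 1), ("c1", 30, 100, 1, 1)] + _c2_balanced()),
     1, 0, 1),
    # 3. AI crossing the centromere: no TAI, but one >=10 Mb breakpoint per arm
    (_profile("ai_cross_cen", [("c1", 0, 20, 1, 1), ("c1", 20, 80, 2, 1),
                               ("c1", 80, 100, 1, 1)] + _c2_balanced()),
     0, 0, 2),
    # 4. whole-chromosome LOH: excluded from LOH, crosses centromere (no TAI),
    #    no internal breakpoint
    (_profile("whole_loh", [("c1", 0, 100, 1, 0)] + _c2_balanced()), 0, 0, 0),
    # 5. interstitial 20 Mb LOH on the q-arm; both breakpoints have >=10 Mb flanks
    (_profile("loh_20mb", [("c1", 0, 60, 1, 1), ("c1", 60, 80, 1, 0),
                           ("c1", 80, 100, 1, 1)] + _c2_balanced()),
     0, 1, 2),
    # 6. sub-threshold 10 Mb LOH: no LOH count, but its two breakpoints remain LSTs
    (_profile("loh_10mb", [("c1", 0, 60, 1, 1), ("c1", 60, 70, 1, 0),
                           ("c1", 70, 100, 1, 1)] + _c2_balanced()),
     0, 0, 2),
    # 7. 12 / 2 / 12 Mb with equal outer states: the 2 Mb interruption is
    #    smoothed away and the outer runs merge -> nothing left to count
    (_profile("smooth_merge", [("c1", 0, 50, 2, 2), ("c1", 50, 62, 2, 2),
                               ("c1", 62, 64, 1, 1), ("c1", 64, 100, 2, 2)]
              + _c2_balanced()),
     0, 0, 0),
    # 8. 12 / 2 / 36 Mb with differing outer states: after smoothing one
    #    breakpoint with 12 and 36 Mb flanks survives
    (_profile("smooth_break", [("c1", 0, 50, 2, 2), ("c1", 50, 62, 2, 2),
                               ("c1", 62, 64, 2, 1), ("c1", 64, 100, 1, 1)]
              + _c2_balanced()),
     0, 0, 1),
    # 9. short telomeric (2,0) run: TAI yes; too short for LOH; 6 Mb flank -> no LST
    (_profile("tai_q_short", [("c1", 0, 94, 1, 1), ("c1", 94, 100, 2, 0)]
              + _c2_balanced()),
     1, 0, 0),
    # 10. homozygous deletion (0,0): balanced by convention -> neither AI nor
    #     LOH; its breakpoint flank (5 Mb) is below the LST threshold
    (_profile("homdel", [("c1", 0, 40, 0, 0), ("c1", 40, 100, 1, 1)]
              + _c2_balanced()),
     0, 0, 0),
    # 11. TAI at both telomeres of one chromosome; each breakpoint is an LST
    (_profile("tai_both", [("c1", 0, 10, 2, 1), ("c1", 10, 90, 1, 1),
                           ("c1", 90, 100, 3, 1)] + _c2_balanced()),
     2, 0, 2),
    # 12. case 5 with the LOH run and a balanced run subdivided: counts identical
    (_profile("split_loh", [("c1", 0, 30, 1, 1), ("c1", 30, 60, 1, 1),
                            ("c1", 60, 70, 1, 0), ("c1", 70, 80, 1, 0),
                            ("c1", 80, 100, 1, 1)] + _c2_balanced()),
     0, 1, 2),
    # 13. copy-neutral LOH at a telomere: counts as AI (TAI) and as LOH
    (_profile("cn_loh", [("c1", 0, 20, 2, 0), ("c1", 20, 100, 1, 1)]
              + _c2_balanced()),
     1, 1, 1),
    # 14. adjacent AI segments with different states merge into one TAI run,
    #     but remain two LST breakpoints (states differ)
    (_profile("merged_tai", [("c1", 0, 10, 2, 1), ("c1", 10, 25, 3, 2),
                             ("c1", 25, 100, 1, 1)] + _c2_balanced()),
     1, 0, 2),
    # 15. events on both chromosomes; on c2 only the breakpoint with a 10 Mb
    #     flank counts (the other flank is 8 Mb)
    (_profile("two_chroms", [("c1", 0, 30, 2, 1), ("c1", 30, 100, 1, 1),
                             ("c2", 0, 37, 1, 1), ("c2", 37, 52, 1, 0),
                             ("c2", 52, 60, 1, 1)]),
     1, 1, 2),
]
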