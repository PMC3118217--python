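"""Printed summary tables used as test inputs.

These are the published per-region SNV accounting numbers and per-locus
haplotype read-count vectors; they serve as inputs to the arithmetic the
package reimplements.
"""

# per region: (sample1 known, sample1 novel, sample2 known, sample2 novel,
#              union known, union novel)
SNV_ACCOUNTING = {
    "CTRL": (574, 41, 595, 48, 771, 77),
    "DEFA": (604, 27, 428, 37, 701, 61),
    "DEFB": (560, 113, 979, 178, 1056, 220),
}

# 48 per-locus rows of the 6-copy sample: (gene, printed read total,
# haplotype read-count vector). In one row (DEFB104, 63:26) the printed
# total (86) disagrees with the sum of its own count vector (89); all other
# rows are internally consistent.
HAPLOTYPE_COUNTS = [
    ("DEFB4", 51, (17, 34)),
    ("DEFB4", 89, (16, 62, 11)),
    ("DEFB103", 45, (10, 26, 9)),
    ("DEFB103", 35, (11, 14, 4, 6)),
    ("DEFB103", 102, (25, 12, 19, 13, 12, 21)),
    ("DEFB103", 33, (8, 6, 11, 8)),
    ("DEFB103", 64, (9, 8, 47)),
    ("SPAG11", 38, (15, 23)),
    ("SPAG11", 60, (29, 16, 15)),
    ("SPAG11", 100, (50, 16, 34)),
    ("SPAG11", 42, (7, 12, 15, 8)),
    ("SPAG11", 63, (22, 11, 12, 18)),
    ("SPAG11", 54, (20, 27, 7)),
    ("SPAG11", 37, (20, 10, 7)),
    ("SPAG11", 35, (19, 16)),
    ("SPAG11", 48, (14, 21, 13)),
    ("SPAG11", 30, (4, 21, 5)),
    ("SPAG11", 32, (8, 14, 10)),
    ("SPAG11", 48, (7, 22, 19)),
    ("SPAG11", 48, (9, 20, 6, 13)),
    ("SPAG11", 62, (13, 18, 13, 7, 11)),
    ("SPAG11", 34, (6, 13, 15)),
    ("SPAG11", 33, (12, 21)),
    ("SPAG11", 40, (6, 8, 26)),
    ("SPAG11", 33, (3, 4, 21, 5)),
    ("SPAG11", 53, (12, 33, 8)),
    ("DEFB104", 36, (17, 7, 12)),
    ("DEFB104", 37, (14, 16, 7)),
    ("DEFB104", 53, (10, 17, 17, 9)),
    ("DEFB104", 32, (20, 12)),
    ("DEFB104", 30, (13, 10, 7)),
    ("DEFB104", 30, (14, 6, 6, 4)),
    ("DEFB104", 86, (63, 26)),
    ("DEFB104", 62, (6, 8, 21, 27)),
    ("DEFB104", 65, (13, 23, 15, 14)),
    ("DEFB104", 31, (6, 6, 6, 5, 8)),
    ("DEFB104", 38, (10, 10, 5, 3, 10)),
    ("DEFB104", 29, (6, 7, 16)),
    ("DEFB104", 31, (9, 14, 8)),
    ("DEFB104", 33, (6, 27)),
    ("DEFB106", 100, (32, 12, 18, 38)),
    ("DEFB106", 77, (21, 13, 31, 12)),
    ("DEFB106", 30, (8, 22)),
    ("DEFB106", 63, (20, 8, 22, 13)),
    ("DEFB106", 61, (17, 6, 24, 14)),
    ("DEFB106", 39, (7, 5, 27)),
    ("DEFB107", 28, (5, 5, 5, 13)),
    ("DEFB107", 97, (78, 19)),
]


def synthetic_union_sets():
    """Two per-sample call sets realising the printed per-region set sizes
    and overlap structure (positions are synthetic placeholders)."""
    sets: dict[str, list[tuple]] = {"s1": [], "s2": []}
    for region, (k1, n1, k2, n2, uk, un) in SNV_ACCOUNTING.items():
        for offset, c1, c2, cu, known in (
            (0, k1, k2, uk, True),
            (1_000_000, n1, n2, un, False),
        ):
            # sample1 takes union positions 1..c1, sample2 the last c2
            sets["s1"].extend(
                (region, offset + i, "C", known) for i in range(1, c1 + 1)
            )
            sets["s2"].extend(
                (region, offset + i, "C", known) for i in range(cu - c2 + 1, cu + 1)
            )
    return sets
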