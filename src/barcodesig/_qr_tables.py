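"""Constant tables for QR model-2 symbols at error-correction level M.

``EC_BLOCKS_M[v]`` = (ec codewords per block, group-1 block count,
group-1 data codewords per block, group-2 block count, group-2 data
codewords per block) for version ``v``. ``ALIGNMENT_POSITIONS[v]`` lists
the row/column centres of the alignment patterns. Both tables are
transcribed from the symbology standard; their internal consistency
with the module-count identity (total codewords derived by counting
non-function modules) is asserted by the test suite for every version.
"""

EC_BLOCKS_M: dict[int, tuple[int, int, int, int, int]] = {
    1: (10, 1, 16, 0, 0),
    2: (16, 1, 28, 0, 0),
    3: (26, 1, 44, 0, 0),
    4: (18, 2, 32, 0, 0),
    5: (24, 2, 43, 0, 0),
    6: (16, 4, 27, 0, 0),
    7: (18, 4, 31, 0, 0),
    8: (22, 2, 38, 2, 39),
    9: (22, 3, 36, 2, 37),
    10: (26, 4, 43, 1, 44),
    11: (30, 1, 50, 4, 51),
    12: (22, 6, 36, 2, 37),
    13: (22, 8, 37, 1, 38),
    14: (24, 4, 40, 5, 41),
    15: (24, 5, 41, 5, 42),
    16: (28, 7, 45, 3, 46),
    17: (28, 10, 46, 1, 47),
    18: (26, 9, 43, 4, 44),
    19: (26, 3, 44, 11, 45),
    20: (26, 3, 41, 13, 42),
    21: (26, 17, 42, 0, 0),
    22: (28, 17, 46, 0, 0),
    23: (28, 4, 47, 14, 48),
    24: (28, 6, 45, 14, 46),
    25: (28, 8, 47, 13, 48),
    26: (28, 19, 46, 4, 47),
    27: (28, 22, 45, 3, 46),
    28: (28, 3, 45, 23, 46),
    29: (28, 21, 45, 7, 46),
    30: (28, 19, 47, 10, 48),
    31: (28, 2, 46, 29, 47),
    32: (28, 10, 46, 23, 47),
    33: (28, 14, 46, 21, 47),
    34: (28, 14, 46, 23, 47),
    35: (28, 12, 47, 26, 48),
    36: (28, 6, 47, 34, 48),
    37: (28, 29, 46, 14, 47),
    38: (28, 13, 46, 32, 47),
    39: (28, 40, 47, 7, 48),
    40: (28, 18, 47, 31, 48),
}

ALIGNMENT_POSITIONS: dict[int, tuple[int, ...]] = {
    1: (),
    2: (6, 18),
    3: (6, 22),
    4: (6, 26),
    5: (6, 30),
    6: (6, 34),
    7: (6, 22, 38),
    8: (6, 24, 42),
    9: (6, 26, 46),
    10: (6, 28, 50),
    11: (6, 30, 54),
    12: (6, 32, 58),
    13: (6, 34, 62),
    14: (6, 26, 46, 66),
    15: (6, 26, 48, 70),
    16: (6, 26, 50, 74),
    17: (6, 30, 54, 78),
    18: (6, 30, 56, 82),
    19: (6, 30, 58, 86),
    20: (6, 34, 62, 90),
    21: (6, 28, 50, 72, 94),
    22: (6, 26, 50, 74, 98),
    23: (6, 30, 54, 78, 102),
    24: (6, 28, 54, 80, 106),
    25: (6, 32, 58, 84, 110),
    26: (6, 30, 58, 86, 114),
    27: (6, 34, 62, 90, 118),
    28: (6, 26, 50, 74, 98, 122),
    29: (6, 30, 54, 78, 102, 126),
    30: (6, 26, 52, 78, 104, 130),
    31: (6, 30, 56, 82, 108, 134),
    32: (6, 34, 60, 86, 112, 138),
    33: (6, 30, 58, 86, 114, 142),
    34: (6, 34, 62, 90, 118, 146),
    35: (6, 30, 54, 78, 102, 126, 150),
    36: (6, 24, 50, 76, 102, 128, 154),
    37: (6, 28, 54, 80, 106, 132, 158),
    38: (6, 32, 58, 84, 110, 136, 162),
    39: (6, 26, 54, 82, 110, 138, 166),
    40: (6, 30, 58, 86, 114, 142, 170),
}


def symbol_size(version: int) -> int:
    return 17 + 4 * version


def data_codewords_m(version: int) -> int:
    ec, g1, d1, g2, d2 = EC_BLOCKS_M[version]
    return g1 * d1 + g2 * d2


def total_codewords_m(version: int) -> int:
    ec, g1, d1, g2, d2 = EC_BLOCKS_M[version]
    return g1 * d1 + g2 * d2 + (g1 + g2) * ec
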