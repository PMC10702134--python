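"""GRCh37 autosome geometry used by the simulator and the aneuploidy caller."""

from __future__ import annotations

#: autosome lengths, bp (GRCh37)
AUTOSOME_LENGTHS = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
}

#: approximate centromere midpoints, bp (GRCh37); used to split p and q arms
CENTROMERE_MIDPOINTS = {
    "1": 125_000_000,
    "2": 93_300_000,
    "3": 91_000_000,
    "4": 50_400_000,
    "5": 48_400_000,
    "6": 61_000_000,
    "7": 59_900_000,
    "8": 45_600_000,
    "9": 49_000_000,
    "10": 40_200_000,
    "11": 53_700_000,
    "12": 35_800_000,
    "13": 17_900_000,
    "14": 17_600_000,
    "15": 19_000_000,
    "16": 36_600_000,
    "17": 24_000_000,
    "18": 17_200_000,
    "19": 26_500_000,
    "20": 27_500_000,
    "21": 13_200_000,
    "22": 14_700_000,
}
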