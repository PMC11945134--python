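"""Bundled worked-example data from a published two-generation maize MABC
program (transgene introgression into an elite inbred, InDel-assisted
background selection).

The per-plant background recovery rates are printed percentages (two
decimals); the scored-marker counts behind them are not published and are
recovered with :func:`mabckit.scoring.infer_scored_marker_count`.
"""

from __future__ import annotations

#: glufosinate survival split (positive, negative) in the BC1 seedlings
BC1_SEGREGATION = (111, 113)

#: printed background recovery rates (%) of the 18 BC1 plants that
#: exceeded the 80% selection threshold
BC1_RECOVERY_PCT: dict[str, float] = {
    "BC1-1": 86.11,
    "BC1-5": 87.03,
    "BC1-6": 81.48,
    "BC1-8": 83.33,
    "BC1-20": 81.48,
    "BC1-27": 87.96,
    "BC1-34": 85.18,
    "BC1-35": 80.55,
    "BC1-36": 81.48,
    "BC1-41": 86.11,
    "BC1-45": 83.33,
    "BC1-46": 87.96,
    "BC1-47": 85.19,
    "BC1-53": 81.48,
    "BC1-54": 80.55,
    "BC1-83": 81.48,
    "BC1-95": 85.18,
    "BC1-101": 84.26,
}

#: the seven BC1 plants used as BC2 parents (phenotype-screened subset)
BC1_PARENT_IDS = ("BC1-1", "BC1-5", "BC1-8", "BC1-35", "BC1-36", "BC1-47", "BC1-83")

#: BC2 family sizes per parent (70 foreground-positive offspring in total)
BC2_FAMILY_SIZES: dict[str, int] = {
    "BC1-1": 8,
    "BC1-5": 12,
    "BC1-8": 11,
    "BC1-35": 9,
    "BC1-36": 11,
    "BC1-47": 8,
    "BC1-83": 11,
}

#: printed background recovery rates (%) of the 70 BC2 plants
BC2_RECOVERY_PCT: dict[str, float] = {
    "BC2-1-1": 92.53, "BC2-1-2": 91.95, "BC2-1-3": 93.10, "BC2-1-4": 90.80,
    "BC2-1-5": 93.60, "BC2-1-6": 91.95, "BC2-1-7": 93.68, "BC2-1-8": 92.44,
    "BC2-5-1": 90.70, "BC2-5-2": 93.10, "BC2-5-3": 93.60, "BC2-5-4": 90.80,
    "BC2-5-5": 94.25, "BC2-5-6": 91.38, "BC2-5-7": 91.95, "BC2-5-8": 87.93,
    "BC2-5-9": 93.68, "BC2-5-10": 91.86, "BC2-5-12": 89.08, "BC2-5-15": 94.77,
    "BC2-8-1": 90.80, "BC2-8-2": 92.53, "BC2-8-3": 93.68, "BC2-8-4": 93.10,
    "BC2-8-6": 94.25, "BC2-8-8": 92.53, "BC2-8-9": 94.25, "BC2-8-10": 93.10,
    "BC2-8-11": 91.95, "BC2-8-12": 89.53, "BC2-8-13": 93.68,
    "BC2-35-1": 90.23, "BC2-35-2": 89.53, "BC2-35-3": 88.51, "BC2-35-4": 91.38,
    "BC2-35-5": 90.80, "BC2-35-6": 90.23, "BC2-35-7": 89.08, "BC2-35-8": 90.23,
    "BC2-35-9": 91.95,
    "BC2-36-1": 93.10, "BC2-36-2": 90.80, "BC2-36-3": 94.25, "BC2-36-4": 90.23,
    "BC2-36-5": 91.95, "BC2-36-7": 92.44, "BC2-36-8": 90.36, "BC2-36-9": 88.37,
    "BC2-36-10": 92.44, "BC2-36-11": 92.35, "BC2-36-12": 95.40,
    "BC2-47-1": 92.44, "BC2-47-2": 93.53, "BC2-47-3": 90.80, "BC2-47-4": 94.25,
    "BC2-47-5": 90.23, "BC2-47-6": 89.66, "BC2-47-7": 94.25, "BC2-47-8": 93.10,
    "BC2-83-1": 94.19, "BC2-83-2": 89.08, "BC2-83-4": 91.38, "BC2-83-5": 93.10,
    "BC2-83-6": 93.10, "BC2-83-7": 92.77, "BC2-83-8": 90.23, "BC2-83-9": 90.80,
    "BC2-83-10": 89.66, "BC2-83-11": 93.02, "BC2-83-12": 92.94,
}
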