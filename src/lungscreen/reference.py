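"""Reference strategy-level results from the original cost-effectiveness study.

The original analysis of risk-stratified LDCT screening for Chinese heavy
smokers reported, for all 36 strategies, discounted cost (thousand CNY per
100,000 people) and QALYs (per 100,000 people), benefit-harm counts, and
the six risk-based strategies flagged on its efficiency frontier.  Those
published numbers serve here as *inputs*: the CEA arithmetic (iNMB, ICER,
frontier construction, benefit-harm ratios) can be re-run on them exactly,
independently of the Markov engine and of any synthetic stand-in tables.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cea_inputs", "reference_benefit_harm", "REFERENCE_FRONTIER",
           "REFERENCE_NO_SCREENING_LC_DEATHS", "REFERENCE_NO_SCREENING_LY_PER_PERSON"]

# (strategy, cost thousand CNY per 100k, QALYs per 100k), ordered by QALYs
_CEA_ROWS = [
    ("no_screening", 845_168, 1_150_366),
    ("H1-MHnone-LMnone-Lnone", 924_335, 1_151_147),
    ("H1-MHone-off-LMone-off-Lnone", 947_457, 1_151_200),
    ("H1-MHone-off-LMone-off-Lone-off", 958_602, 1_151_202),
    ("H1-MHone-off-LMnone-Lnone", 937_823, 1_151_247),
    ("H1-MH3-LMone-off-Lnone", 999_095, 1_152_081),
    ("H1-MH3-LMone-off-Lone-off", 1_010_241, 1_152_083),
    ("H1-MH3-LMnone-Lnone", 989_462, 1_152_127),
    ("H1-MH2-LM3-Lnone", 1_041_867, 1_152_229),
    ("H1-MH2-LMone-off-Lnone", 1_018_091, 1_152_258),
    ("H1-MH2-LMone-off-Lone-off", 1_029_237, 1_152_260),
    ("H1-MH1-LM1-Lnone", 1_123_224, 1_152_277),
    ("H1-MH2-LMnone-Lnone", 1_008_458, 1_152_305),
    ("H1-MH1-LMone-off-Lnone", 1_047_048, 1_152_354),
    ("H1-MH1-LMone-off-Lone-off", 1_058_193, 1_152_356),
    ("H1-MH1-LM2-Lnone", 1_090_559, 1_152_357),
    ("H1-MH1-LMnone-Lnone", 1_037_415, 1_152_401),
    ("H1-MH3-LM3-Lnone", 1_039_447, 1_152_411),
    ("H1-MH3-LM3-Lone-off", 1_050_593, 1_152_413),
    ("H1-MH2-LM3-Lone-off", 1_069_589, 1_152_591),
    ("H1-MH2-LM2-Lnone", 1_078_179, 1_152_621),
    ("H1-MH2-LM2-Lone-off", 1_089_324, 1_152_624),
    ("H1-MH1-LM1-Lone-off", 1_150_946, 1_152_639),
    ("H1-MH1-LM3-Lnone", 1_087_400, 1_152_684),
    ("H1-MH1-LM3-Lone-off", 1_098_545, 1_152_687),
    ("H1-MH1-LM2-Lone-off", 1_118_281, 1_152_720),
    ("H1-MH3-LM3-L3", 1_114_292, 1_153_247),
    ("H1-MH2-LM3-L3", 1_133_288, 1_153_425),
    ("H1-MH2-LM2-L3", 1_153_023, 1_153_458),
    ("H1-MH1-LM1-L3", 1_214_645, 1_153_473),
    ("H1-MH1-LM3-L3", 1_162_244, 1_153_520),
    ("H1-MH1-LM2-L3", 1_181_980, 1_153_554),
    ("H1-MH2-LM2-L2", 1_177_849, 1_153_596),
    ("H1-MH1-LM1-L1", 1_279_258, 1_153_601),
    ("H1-MH1-LM1-L2", 1_239_470, 1_153_611),
    ("H1-MH1-LM2-L2", 1_206_805, 1_153_692),
]

#: Risk-based strategies flagged on the published efficiency frontier.
REFERENCE_FRONTIER = (
    "H1-MH3-LMnone-Lnone",
    "H1-MH2-LMnone-Lnone",
    "H1-MH3-LM3-L3",
    "H1-MH2-LM3-L3",
    "H1-MH2-LM2-L2",
    "H1-MH1-LM2-L2",
)

# (strategy, screens, deaths averted, LY gained) per 100,000 people
_BH_ROWS = [
    ("H1-MH1-LM1-L1", 1_071_810, 770, 13_949),
    ("H1-MH1-LM2-L2", 811_880, 707, 12_599),
    ("H1-MH2-LM2-L2", 729_660, 665, 11_893),
    ("H1-MH2-LM3-L3", 591_440, 606, 10_614),
    ("H1-MH3-LM3-L3", 549_100, 569, 9_999),
    ("H1-MH2-LMnone-Lnone", 295_680, 382, 5_769),
    ("H1-MH3-LMnone-Lnone", 253_350, 344, 5_154),
    ("H1-MHnone-LMnone-Lnone", 148_000, 173, 2_301),
]

#: Reported lung-cancer deaths per 100,000 people without screening.
REFERENCE_NO_SCREENING_LC_DEATHS = 2162.0
#: Reported undiscounted life-years per person without screening.
REFERENCE_NO_SCREENING_LY_PER_PERSON = 18.305


def reference_cea_inputs() -> pd.DataFrame:
    """Published per-strategy cost (CNY, converted from thousands) and QALYs."""
    df = pd.DataFrame(_CEA_ROWS, columns=["strategy", "cost_thousand", "qalys"])
    df["cost"] = df["cost_thousand"] * 1000.0
    return df


def reference_benefit_harm() -> pd.DataFrame:
    """Published screens / deaths-averted / life-years-gained per 100,000."""
    return pd.DataFrame(_BH_ROWS, columns=["strategy", "screens", "deaths_averted", "ly_gained"])
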