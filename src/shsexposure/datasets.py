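"""Published reference data from the 15-prison Scottish baseline survey.

The survey printed its per-prison area-monitoring results — 6-day measurement
duration, benchmark exceedance percentages, maximum and mean (SD) PM2.5,
matched ambient-station means, and the per-monitor passive-nicotine results
with their QC annotations.  Those printed values are the inputs for the
desk-scale cross-prison statistics (pooled medians, the processed nicotine
median and the PM–nicotine agreement), so they ship here as small inline
tables.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .nicotine import NicotineMeasurement

__all__ = [
    "load_area_survey",
    "load_nicotine_survey",
    "COHORT_MEDIAN_INCREMENT",
    "COHORT_SUBSAMPLE_N",
]

# Cohort-level salivary-cotinine figures from the same survey: the median
# shift increment (ng/ml) over the measurable sub-sample and that sub-sample's
# size.  Inputs to the cohort-level biomarker→PM conversion.
COHORT_MEDIAN_INCREMENT = 0.138
COHORT_SUBSAMPLE_N = 149

# Per-prison area monitoring: duration (minutes), % of 1-minute measurements
# above 10 / 25 / 246 µg/m³, maximum and mean (SD) PM2.5, and the matched
# ambient-station mean (SD), all µg/m³.
_AREA_CSV = """\
prison,duration_min,pct_gt10,pct_gt25,pct_gt246,max_pm,mean_pm,sd_pm,ambient_mean,ambient_sd
P1,8635,40,16,0,64,11.2,9.4,6.6,6.9
P2,8644,99,93,0,222,54.6,37.5,11.4,4.9
P3,8610,86,50,0,62,28.8,16.7,10.5,3.7
P4,8638,98,78,20,1009,135.9,189.4,5.2,11.4
P5,7301,89,70,3.1,569,48.6,62.4,9.4,4.1
P6,8641,93,63,0,132,28.5,15.8,5.9,2.6
P7,8640,97,71,0,171,36,15.1,6.4,2.2
P8,8700,94,66,0,198,31.7,16.2,22.8,6.2
P9,8642,87,45,0,162,23.4,13.5,5.3,1.4
P10,8642,81,55,0.1,272,49.2,48.6,5.7,2.1
P11,8701,84,57,0.1,335,32,20.8,11.5,6.0
P12,8645,68,39,0,111,19.8,12.1,12.6,5.0
P13,8627,94,69,0,142,35.3,21.0,5.3,1.6
P14,8704,87,69,0.1,466,31.1,18.8,6.5,4.7
P15,8661,40,7,0,125,10.5,8.7,7.7,5.5
"""

# Per-monitor passive nicotine (µg/m³ over the 6-day period).  P2 and P12
# deployed duplicate pairs; P3's monitor was tampered with (holed membrane)
# and was never analysed; P1 and P11 ran non-contemporaneously with the PM
# device; P13/P15 were below the 0.031 µg/m³ LOD.  B1/B2 are unexposed field
# blanks, both below the LOD.
_NICOTINE_CSV = """\
prison,monitor,concentration,duration_minutes,field_blank,duplicate_of,tampered,contemporaneous
P1,M01,0.349,8635,0,,0,0
P2,M02a,0.637,8644,0,,0,1
P2,M02b,0.546,8644,0,M02a,0,1
P3,M03,,8610,0,,1,1
P4,M04,1.651,8638,0,,0,1
P5,M05,0.608,7301,0,,0,1
P6,M06,0.436,8641,0,,0,1
P7,M07,0.159,8640,0,,0,1
P8,M08,0.323,8700,0,,0,1
P9,M09,0.169,8642,0,,0,1
P10,M10,0.546,8642,0,,0,1
P11,M11,0.101,8701,0,,0,0
P12,M12a,0.137,8645,0,,0,1
P12,M12b,0.230,8645,0,M12a,0,1
P13,M13,<LOD,8627,0,,0,1
P14,M14,0.319,8704,0,,0,1
P15,M15,<LOD,8661,0,,0,1
B1,BLK1,<LOD,8640,1,,0,1
B2,BLK2,<LOD,8640,1,,0,1
"""


def load_area_survey() -> pd.DataFrame:
    """Per-prison area-monitoring summary table, one row per prison."""
    return pd.read_csv(_io.StringIO(_AREA_CSV))


def load_nicotine_survey() -> list[NicotineMeasurement]:
    """Per-monitor passive-nicotine results with QC flags."""
    out = []
    for _, r in pd.read_csv(_io.StringIO(_NICOTINE_CSV)).iterrows():
        tok = r["concentration"]
        censored = isinstance(tok, str) and tok.strip() == "<LOD"
        conc = None if (censored or pd.isna(tok)) else float(tok)
        dup = r["duplicate_of"]
        out.append(
            NicotineMeasurement(
                prison_id=str(r["prison"]),
                monitor_id=str(r["monitor"]),
                concentration=conc,
                duration_minutes=float(r["duration_minutes"]),
                censored=censored,
                field_blank=bool(r["field_blank"]),
                duplicate_of=None if pd.isna(dup) else str(dup),
                tampered=bool(r["tampered"]),
                contemporaneous=bool(r["contemporaneous"]),
            )
        )
    return out
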