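"""Published summary tables from the Córdoba *Vulpia geniculata* survey.

The raw per-point field observations were never deposited; what the study
printed are (a) the ten sampling sites, (b) per-date descriptive statistics
with the m ± 3s outlier thresholds for 2004–2006, and (c) per-date
cross-validation regression coefficients.  These ship here as plain-text
fixtures: the sites seed realistic synthetic networks, the descriptive table
is the arithmetic surface the screening module is checked against, and the
regression coefficients support qualitative comparison only.
"""

from __future__ import annotations

import io

import pandas as pd

from .data import SamplingPoint, Zone

__all__ = [
    "cordoba_network",
    "descriptive_reference",
    "cv_reference",
    "consistent_threshold_cells",
]

_SAMPLING_POINTS_CSV = """\
id,altitude,x,y,zone
Sotos de la Albolafia,92,343274,4193395,termomediterranean
Arroyo de Rabanales,109,357483,4196492,termomediterranean
Barrio Naranjo,146,344300,4196752,termomediterranean
Asland,184,345252,4198511,termomediterranean
Algeria de la Sierra,217,344926,4199407,termomediterranean
La Palomera,251,342737,4198985,mesomediterranean
Santo Domingo,368,341758,4200722,mesomediterranean
Cuesta del 14%,511,341181,4201771,mesomediterranean
La Conejera,555,340584,4201852,mesomediterranean
Los Villares,585,341149,4203129,mesomediterranean
"""

# year, survey date (ISO), printed mean/variance/min/max/n and printed thresholds
_DESCRIPTIVE_CSV = """\
year,date,mean,variance,minimum,maximum,n,upper_printed,lower_printed
2004,2004-04-23,1.04,0.32,0.00,1.75,7,2.74,-0.67
2004,2004-04-30,1.54,0.40,0.50,2.25,7,3.44,-0.37
2004,2004-05-07,2.11,0.33,1.25,2.75,7,3.83,0.38
2004,2004-05-14,2.54,0.24,1.75,3.00,7,4.00,1.07
2004,2004-05-21,3.04,0.26,2.25,3.50,7,4.56,1.51
2004,2004-05-28,3.68,0.31,2.75,4.00,7,5.34,2.02
2005,2005-04-22,0.42,0.14,0.00,1.00,6,1.55,-0.71
2005,2005-04-29,1.18,0.26,0.50,2.00,7,2.72,-0.37
2005,2005-05-06,2.11,0.48,1.50,3.50,7,4.18,0.04
2005,2005-05-13,2.82,0.41,2.25,4.00,7,4.74,0.90
2005,2005-05-20,3.25,0.20,2.75,4.00,7,4.59,1.91
2006,2006-04-13,0.64,0.14,0.00,1.25,7,1.78,-0.49
2006,2006-04-20,1.14,0.18,0.75,2.00,7,2.43,-0.15
2006,2006-04-27,1.57,0.16,1.00,2.25,7,2.77,0.37
2006,2006-05-04,2.18,0.16,1.50,2.75,7,3.38,0.98
2006,2006-05-11,2.61,0.16,2.00,3.25,7,3.82,1.39
2006,2006-05-18,3.18,0.20,2.50,3.75,7,4.53,1.83
2006,2006-05-25,3.79,0.15,3.00,4.00,7,4.97,2.61
"""

# leave-one-out cross-validation regression coefficients per survey date
_CV_CSV = """\
year,date,regression_coefficient
2004,2004-04-23,0.93
2004,2004-04-30,1.14
2004,2004-05-07,1.12
2004,2004-05-14,1.12
2004,2004-05-21,0.99
2004,2004-05-28,0.78
2005,2005-04-22,0.73
2005,2005-04-29,0.99
2005,2005-05-06,0.41
2005,2005-05-13,0.48
2005,2005-05-20,0.47
2006,2006-04-13,0.59
2006,2006-04-20,0.47
2006,2006-04-27,0.41
2006,2006-05-04,0.38
2006,2006-05-11,0.80
2006,2006-05-18,0.92
2006,2006-05-25,1.12
"""

# The printed thresholds that agree (to the printed 2 dp) with m ± 3·sqrt(variance)
# recomputed from the printed mean and variance of the same column.  The remaining
# cells were evidently derived from unrounded statistics and differ by 0.01–0.02.
_CONSISTENT_CELLS = [
    # (key, date ISO, bound, printed value)
    ("t1", "2004-04-23", "upper", 2.74),
    ("t2", "2004-05-14", "lower", 1.07),
    ("t3", "2005-05-13", "upper", 4.74),
    ("t4", "2005-05-13", "lower", 0.90),
    ("t5", "2005-05-20", "upper", 4.59),
    ("t6", "2005-05-20", "lower", 1.91),
    ("t7", "2006-04-27", "upper", 2.77),
    ("t8", "2006-04-27", "lower", 0.37),
]


def cordoba_network() -> list[SamplingPoint]:
    """The study's ten monitoring sites (5 termo- + 5 mesomediterranean)."""
    df = pd.read_csv(io.StringIO(_SAMPLING_POINTS_CSV))
    return [
        SamplingPoint(
            id=r.id, x=float(r.x), y=float(r.y), altitude=float(r.altitude),
            zone=Zone.parse(r.zone),
        )
        for r in df.itertuples(index=False)
    ]


def descriptive_reference() -> pd.DataFrame:
    """Printed per-date descriptive statistics and outlier thresholds, 2004–2006."""
    return pd.read_csv(io.StringIO(_DESCRIPTIVE_CSV))


def cv_reference() -> pd.DataFrame:
    """Printed per-date cross-validation regression coefficients (qualitative only)."""
    return pd.read_csv(io.StringIO(_CV_CSV))


def consistent_threshold_cells() -> pd.DataFrame:
    """Threshold cells that are exactly reproducible from the printed mean/variance."""
    return pd.DataFrame(
        _CONSISTENT_CELLS, columns=["key", "date", "bound", "printed"]
    )
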