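"""Published reference data for the 35-decoction bitterness study.

Two tables are bundled:

* the five-rank bitterness scale (rank I-V, each anchored to a berberine
  hydrochloride reference solution), and
* the human-panel results for the 35 Chinese herbal decoctions
  (per-sample mean +/- sd bitterness intensity and decoction pH).

The accompanying 35x7 e-tongue sensor matrix was never deposited, which is
why sensor data in this package are synthetic (see
:mod:`bittertongue.synthetic`).
"""

from __future__ import annotations

import pandas as pd

#: The seven cross-sensitive bitterness sensors of the Astree II array.
SENSOR_NAMES = ("ZZ", "CA", "DA", "BA", "GA", "BB", "AB")

#: (rank, lower bound, upper bound, upper-closed?, reference conc. mg/mL)
#: Intervals are half-open [lo, hi) except rank V, closed at both ends.
RANK_SCALE = (
    ("I", 0.5, 1.5, False, 0.0),
    ("II", 1.5, 2.5, False, 0.01),
    ("III", 2.5, 3.5, False, 0.05),
    ("IV", 3.5, 4.5, False, 0.1),
    ("V", 4.5, 5.5, True, 0.5),
)

# no, pinyin name, panel mean, panel sd, pH
_PANEL_ROWS = [
    (1, "Chuanmutong", 0.70, 0.24, 6.71),
    (2, "Sangzhi", 0.67, 0.23, 6.57),
    (3, "Gouteng", 0.70, 0.25, 6.72),
    (4, "Cheqianzi", 0.71, 0.20, 5.82),
    (5, "Zhuru", 1.24, 0.38, 6.80),
    (6, "Mingdangshen", 0.73, 0.30, 6.45),
    (7, "Zelan", 1.19, 0.62, 6.20),
    (8, "Fuling", 0.63, 0.17, 6.74),
    (9, "Tongcao", 0.64, 0.14, 7.15),
    (10, "Cangerzi", 1.21, 0.50, 6.81),
    (11, "Duzhong", 1.26, 0.57, 6.15),
    (12, "Zexie", 0.95, 0.50, 7.14),
    (13, "Cheqiancao", 1.26, 0.62, 5.46),
    (14, "Zhebeimu", 1.82, 0.39, 6.10),
    (15, "Tianhuafeng", 0.91, 0.36, 6.55),
    (16, "Qiancao", 1.81, 0.66, 5.83),
    (17, "Baiwei", 1.67, 0.62, 5.91),
    (18, "Yimucao", 2.54, 0.84, 6.09),
    (19, "Yanhusuo", 2.80, 0.40, 6.59),
    (20, "Fangji", 3.01, 0.42, 6.76),
    (21, "Huangqin", 3.28, 0.53, 5.36),
    (22, "Beidougen", 2.03, 0.89, 6.33),
    (23, "Baiji", 1.78, 0.92, 4.57),
    (24, "Dangyao", 3.92, 0.53, 5.75),
    (25, "Kulianpi", 1.47, 0.84, 6.78),
    (26, "Lianzixin", 3.47, 1.17, 6.86),
    (27, "Qinpi", 1.40, 0.63, 6.18),
    (28, "Huanglian", 4.45, 0.77, 7.70),
    (29, "Kushen", 4.78, 0.63, 6.91),
    (30, "Longdan", 4.55, 0.68, 5.79),
    (31, "Huangbo", 4.66, 0.69, 6.56),
    (32, "Yadanzi", 1.10, 0.50, 8.56),
    (33, "Chuanxinlian", 4.04, 0.52, 6.70),
    (34, "Huhuanglian", 4.67, 0.54, 4.65),
    (35, "Kumu", 4.08, 0.75, 7.89),
]

#: Sample ids (1-based) excluded from the published robust calibration:
#: five flagged outliers plus one borderline sample removed manually.
PUBLISHED_EXCLUDED_IDS = (18, 23, 25, 26, 27, 32)

#: The one published good-leverage sample, retained despite its large
#: score distance.
PUBLISHED_GOOD_LEVERAGE_ID = 1


def reference_panel() -> pd.DataFrame:
    """The 35-sample human-panel table as a DataFrame.

    Columns: ``sample_id``, ``name``, ``mean``, ``sd``, ``pH``.
    """
    return pd.DataFrame(
        _PANEL_ROWS, columns=["sample_id", "name", "mean", "sd", "pH"]
    )
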