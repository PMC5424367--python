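"""Published proximate-determinant decompositions for Uganda (DHS 2006, 2011).

National estimates of the marriage, contraception, postpartum and
abortion indices and the total fertility rate, stratified by religion,
region, residence, wealth quintile and education, as published for the
2006 and 2011 Uganda Demographic and Health Surveys. These serve as the
package's worked example: feeding each row's four indices through the
aggregate model with TF = 15.3 reproduces the published TFR.

The underlying survey microdata are registration-gated and are not
shipped; only these aggregate estimates are.
"""
from __future__ import annotations

import pandas as pd

_COLUMNS = ["variable", "category", "cm", "cc", "ci", "ca", "tfr"]

_UGANDA_2006 = [
    ("religion", "catholic", 0.756688, 0.81124, 0.72359, 1.0, 6.8),
    ("religion", "protestant", 0.688570, 0.76740, 0.74156, 1.0, 6.0),
    ("religion", "muslim", 0.723129, 0.71102, 0.75700, 1.0, 6.0),
    ("religion", "other", 0.677555, 0.78402, 0.73206, 1.0, 5.9),
    ("region", "kampala", 0.532694, 0.52907, 0.81400, 1.0, 3.5),
    ("region", "central", 0.680401, 0.66009, 0.76805, 1.0, 5.3),
    ("region", "eastern", 0.776696, 0.79588, 0.74267, 1.0, 7.0),
    ("region", "northern", 0.773491, 0.90037, 0.69493, 1.0, 7.4),
    ("region", "western", 0.749218, 0.77022, 0.73475, 1.0, 6.5),
    ("residence", "rural", 0.761407, 0.81240, 0.72966, 1.0, 6.9),
    ("residence", "urban", 0.562910, 0.56882, 0.79239, 1.0, 3.9),
    ("wealth_quintile", "poorest", 0.815166, 0.92263, 0.71200, 1.0, 8.2),
    ("wealth_quintile", "poorer", 0.767808, 0.85478, 0.71023, 1.0, 7.1),
    ("wealth_quintile", "middle", 0.739220, 0.81104, 0.71968, 1.0, 6.6),
    ("wealth_quintile", "richer", 0.759015, 0.73921, 0.75614, 1.0, 6.5),
    ("wealth_quintile", "richest", 0.577128, 0.53849, 0.79618, 1.0, 3.8),
    ("education", "none", 0.830933, 0.89279, 0.70547, 1.0, 8.0),
    ("education", "primary", 0.748226, 0.78791, 0.73233, 1.0, 6.6),
    ("education", "secondary+", 0.611473, 0.56484, 0.79904, 1.0, 4.2),
    ("TOTAL", "TOTAL", 0.722717, 0.78179, 0.73502, 1.0, 6.4),
]

_UGANDA_2011 = [
    ("religion", "catholic", 0.739750, 0.75710, 0.75103, 1.0, 6.4),
    ("religion", "protestant", 0.686338, 0.68546, 0.77042, 1.0, 5.5),
    ("religion", "muslim", 0.765173, 0.70558, 0.77160, 1.0, 6.4),
    ("religion", "other", 0.796222, 0.65513, 0.75729, 1.0, 6.0),
    ("region", "kampala", 0.568926, 0.54316, 0.83333, 1.0, 3.9),
    ("region", "central", 0.718897, 0.64366, 0.79491, 1.0, 5.6),
    ("region", "eastern", 0.758391, 0.74057, 0.77042, 1.0, 6.6),
    ("region", "northern", 0.723603, 0.84672, 0.72150, 1.0, 6.8),
    ("region", "western", 0.721989, 0.68546, 0.75358, 1.0, 5.7),
    ("residence", "rural", 0.780517, 0.76701, 0.74822, 1.0, 6.9),
    ("residence", "urban", 0.592744, 0.57047, 0.81136, 1.0, 4.2),
    ("wealth_quintile", "poorest", 0.821068, 0.89191, 0.73233, 1.0, 8.2),
    ("wealth_quintile", "poorer", 0.797797, 0.78723, 0.73665, 1.0, 7.1),
    ("wealth_quintile", "middle", 0.749112, 0.71637, 0.73719, 1.0, 6.1),
    ("wealth_quintile", "richer", 0.741234, 0.66709, 0.77131, 1.0, 5.8),
    ("wealth_quintile", "richest", 0.584853, 0.54365, 0.81934, 1.0, 4.0),
    ("education", "none", 0.820628, 0.87626, 0.72595, 1.0, 8.0),
    ("education", "primary", 0.765763, 0.72988, 0.75047, 1.0, 6.4),
    ("education", "secondary+", 0.598991, 0.56241, 0.82203, 1.0, 4.2),
    ("TOTAL", "TOTAL", 0.724311, 0.71870, 0.76190, 1.0, 6.1),
]


def uganda_indices(year: int) -> pd.DataFrame:
    """Published index decomposition for Uganda, ``year`` in {2006, 2011}."""
    if year == 2006:
        rows = _UGANDA_2006
    elif year == 2011:
        rows = _UGANDA_2011
    else:
        raise ValueError(f"no published decomposition for year {year}")
    return pd.DataFrame(rows, columns=_COLUMNS)
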