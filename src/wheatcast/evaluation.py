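"""Accuracy metrics and data-splitting protocols.

Metrics follow the conventions of county-yield validation studies:
R-squared about the mean observed yield, RMSE in kg/ha, mean absolute
relative error (MRE) in percent, and the per-county-year accuracy ratio
EY/OY x 100 used in cross-region validation tables (values above 100
indicate overestimation).

Splits: seeded 80/20 train/test, seeded k-fold, and leave-one-year-out
(all samples of one season held out, testing temporal generalization).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .containers import SampleSet

__all__ = [
    "MetricsReport",
    "r2",
    "rmse",
    "mre",
    "accuracy_ratio",
    "compute_metrics",
    "split_train_test",
    "kfold",
    "leave_one_year_out",
    "cross_region_reference_table",
]


@dataclass
class MetricsReport:
    """R-squared, RMSE (kg/ha), MRE (%) and the sample count behind them."""

    r2: float
    rmse: float
    mre: float
    n: int
    accuracy: float | None = None  # mean accuracy ratio (%), when computed

    def to_dict(self) -> dict:
        return asdict(self)


def _pair(observed, estimated) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(observed, float).ravel()
    y = np.asarray(estimated, float).ravel()
    if x.shape != y.shape:
        raise ValueError("observed and estimated must have the same length")
    return x, y


def r2(observed, estimated) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of the observed yields.
    """
    x, y = _pair(observed, estimated)
    if len(x) < 2:
        raise ValueError("need at least 2 samples for R^2")
    ss_tot = float(((x - x.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance")
    ss_res = float(((x - y) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(observed, estimated) -> float:
    """Root mean squared error (same units as the yields, kg/ha)."""
    x, y = _pair(observed, estimated)
    if len(x) < 1:
        raise ValueError("need at least 1 sample")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def mre(observed, estimated) -> float:
    """Mean absolute relative error, percent.

    mean(|x_i - y_i| / x_i) x 100.  The absolute value makes the statistic
    an error magnitude (signed relative errors would cancel).
    """
    x, y = _pair(observed, estimated)
    if np.any(x <= 0):
        raise ValueError("observed yields must be positive for MRE")
    return float(np.mean(np.abs(x - y) / x) * 100.0)


def accuracy_ratio(official, estimated) -> np.ndarray | float:
    """Accuracy ratio EY/OY x 100, reported to 2 decimals.

    Values above 100 indicate overestimation of the official yield.
    """
    oy = np.asarray(official, float)
    ey = np.asarray(estimated, float)
    if np.any(oy <= 0):
        raise ValueError("official yields must be positive")
    ac = np.round(ey / oy * 100.0, 2)
    return float(ac) if ac.ndim == 0 else ac


def compute_metrics(observed, estimated) -> MetricsReport:
    """Convenience bundle of the three headline metrics."""
    x, y = _pair(observed, estimated)
    return MetricsReport(r2=r2(x, y), rmse=rmse(x, y), mre=mre(x, y), n=len(x))


# ---------------------------------------------------------------------------
# splits


def split_train_test(ids, fraction: float = 0.8, seed: int = 0):
    """Seeded uniform shuffle; first ceil(fraction * N) ids go to train."""
    ids = np.asarray(ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.ceil(fraction * n))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def kfold(ids, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Seeded partition into k disjoint folds with sizes differing by <= 1."""
    ids = np.asarray(ids)
    n = len(ids)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def leave_one_year_out(samples: SampleSet, test_year: int) -> tuple[SampleSet, SampleSet]:
    """All samples of ``test_year`` to test, everything else to train."""
    years = samples.years
    if test_year not in years:
        raise ValueError(f"year {test_year} not present in the sample set")
    test_idx = np.nonzero(years == test_year)[0]
    train_idx = np.nonzero(years != test_year)[0]
    return samples.take(train_idx), samples.take(test_idx)


# ---------------------------------------------------------------------------
# cross-region reference table
#
# Published official (OY) vs estimated (EY) winter wheat yields, kg/ha, for
# three counties over 2011-2020 (27 county-years with data).  Used to
# validate the accuracy-ratio arithmetic and as the worked example of the
# Table-style cross-region report.

_REFERENCE_ROWS = [
    # county, year, OY, EY
    ("Juye", 2011, 5982.00, 5515.33),
    ("Juye", 2012, 5595.50, 5581.36),
    ("Juye", 2013, 6220.55, 5806.00),
    ("Juye", 2014, 6298.56, 5256.34),
    ("Juye", 2015, 6519.32, 5518.70),
    ("Juye", 2016, 6594.21, 5468.75),
    ("Juye", 2017, 6672.25, 5633.01),
    ("Juye", 2018, 5842.56, 5144.94),
    ("Juye", 2019, 6183.53, 5420.34),
    ("Juye", 2020, 6382.81, 5455.10),
    ("Pingyin", 2011, 5289.32, 4858.18),
    ("Pingyin", 2012, 5379.58, 5233.53),
    ("Pingyin", 2013, 5065.79, 5129.78),
    ("Pingyin", 2014, 5076.48, 5176.06),
    ("Pingyin", 2015, 5231.59, 5308.63),
    ("Pingyin", 2016, 5186.58, 5358.89),
    ("Pingyin", 2017, 5075.33, 5403.32),
    ("Pingyin", 2018, 4825.31, 5247.12),
    ("Guangrao", 2012, 7022.00, 6043.81),
    ("Guangrao", 2013, 6862.00, 5880.17),
    ("Guangrao", 2014, 6908.00, 5895.60),
    ("Guangrao", 2015, 6702.00, 5667.40),
    ("Guangrao", 2016, 6325.00, 5497.64),
    ("Guangrao", 2017, 6363.00, 5434.58),
    ("Guangrao", 2018, 5965.00, 5322.84),
    ("Guangrao", 2019, 5292.00, 5533.20),
    ("Guangrao", 2020, 6506.00, 5396.51),
]


def cross_region_reference_table() -> pd.DataFrame:
    """The bundled cross-region validation table with recomputed accuracy.

    Columns: county, year, oy (official yield), ey (estimated yield),
    accuracy (EY/OY x 100).
    """
    df = pd.DataFrame(_REFERENCE_ROWS, columns=["county", "year", "oy", "ey"])
    df["accuracy"] = accuracy_ratio(df["oy"].to_numpy(), df["ey"].to_numpy())
    return df
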