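"""Oxidative-stress scoring: MitoSOX high-ROS cell fractions, ABTS/Trolox
antioxidant capacity, and 2^-ddCt relative gene expression — each with a
paired seeded synthetic-data generator.

MitoSOX rule: a cell is high-ROS when its fluorescence is at least
median + (median - 5th percentile) of the region's intensity distribution;
the count of high-ROS cells is divided by the DAPI total for the region.

Antioxidant capacity: the lag before ABTS oxidation (absorbance rise at
734 nm) is read off the sample curve and converted to a Trolox-equivalent
concentration through a least-squares standard line lag = a + b * conc.

qPCR: dCt = Ct_gene - Ct_reference per sample, ddCt = dCt - mean control
dCt, fold change = 2^(-ddCt); the control-group mean fold is 1 by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import ParameterError

__all__ = [
    "CellIntensityTable",
    "AntioxidantRun",
    "QPCRTable",
    "high_ros_threshold",
    "high_ros_fraction",
    "measure_lag_time",
    "antioxidant_capacity",
    "ddct_fold_change",
    "simulate_cell_intensities",
    "simulate_antioxidant_run",
    "simulate_qpcr_table",
]


# ---------------------------------------------------------------------------
# MitoSOX high-ROS scoring
# ---------------------------------------------------------------------------


@dataclass
class CellIntensityTable:
    """Per-cell fluorescence with region/animal labels plus DAPI totals.

    cells: DataFrame with columns animal, region, intensity.
    dapi: DataFrame with columns animal, region, dapi_total (total cell count
    per region; must be >= the number of measured cells in that region).
    """

    cells: pd.DataFrame
    dapi: pd.DataFrame

    def __post_init__(self):
        for col in ("animal", "region", "intensity"):
            if col not in self.cells.columns:
                raise ParameterError(f"cells table missing column {col!r}")
        for col in ("animal", "region", "dapi_total"):
            if col not in self.dapi.columns:
                raise ParameterError(f"dapi table missing column {col!r}")
        if (self.cells["intensity"] < 0).any():
            raise ParameterError("intensities must be >= 0")
        counts = self.cells.groupby(["animal", "region"]).size()
        dapi = self.dapi.set_index(["animal", "region"])["dapi_total"]
        for key, n_meas in counts.items():
            if key in dapi.index and dapi.loc[key] < n_meas:
                raise ParameterError(f"dapi_total < measured cells for {key}")


def high_ros_threshold(intensities: Sequence[float]) -> float:
    """High-ROS intensity cutoff: median + (median - 5th percentile).

    Percentiles use linear interpolation between order statistics. With
    fewer than 20 cells the 5th percentile is unstable; a warning (not an
    error) is raised. Cells at or above the threshold count as high-ROS, so
    a degenerate all-equal distribution scores every cell high-ROS.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ParameterError("no intensities")
    if x.size < 20:
        warnings.warn("fewer than 20 cells: 5th percentile is unstable", stacklevel=2)
    med = float(np.median(x))
    p5 = float(np.percentile(x, 5.0))  # linear interpolation (numpy default)
    return med + (med - p5)


def high_ros_fraction(
    table: CellIntensityTable,
    threshold_scope: str = "per_region",
) -> tuple[pd.DataFrame, pd.Series]:
    """High-ROS fraction per region and its unweighted mean per animal.

    fraction = (# cells with intensity >= threshold) / dapi_total. The
    threshold is computed per region by default, or from all of an animal's
    cells pooled (threshold_scope="pooled").
    """
    if threshold_scope not in ("per_region", "pooled"):
        raise ParameterError("threshold_scope must be 'per_region' or 'pooled'")
    dapi = table.dapi.set_index(["animal", "region"])["dapi_total"]
    rows = []
    pooled_thr = {
        a: high_ros_threshold(g["intensity"].to_numpy())
        for a, g in table.cells.groupby("animal")
    } if threshold_scope == "pooled" else None
    for (animal, region), g in table.cells.groupby(["animal", "region"]):
        total = int(dapi.loc[(animal, region)])
        if total == 0:
            raise ParameterError(f"dapi_total is zero for {(animal, region)}")
        thr = (
            pooled_thr[animal]
            if pooled_thr is not None
            else high_ros_threshold(g["intensity"].to_numpy())
        )
        n_high = int((g["intensity"].to_numpy() >= thr).sum())
        rows.append(
            {"animal": animal, "region": region, "threshold": thr,
             "n_high": n_high, "dapi_total": total, "fraction": n_high / total}
        )
    regions = pd.DataFrame(rows)
    per_animal = regions.groupby("animal")["fraction"].mean()
    return regions, per_animal


def simulate_cell_intensities(
    n_animals: int = 6,
    regions: Sequence[str] = ("FL_L", "FL_R", "HL_L", "HL_R"),
    cells_per_region: int = 200,
    high_ros_proportion: float = 0.1,
    low_mode: float = 100.0,
    low_sigma: float = 0.25,
    high_multiplier: float = 4.0,
    extra_unmeasured: int = 20,
    seed: int = 0,
) -> CellIntensityTable:
    """Two-population generator: a lognormal low-fluorescence mode plus a
    high-ROS subpopulation at proportion `high_ros_proportion` with
    `high_multiplier`-fold intensity. dapi_total exceeds the measured count
    by `extra_unmeasured` (cells visible in DAPI but not scored)."""
    if not (0 <= high_ros_proportion <= 1):
        raise ParameterError("high_ros_proportion must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cells, dapi = [], []
    for a in range(n_animals):
        animal = f"animal{a+1}"
        for region in regions:
            n_high = rng.binomial(cells_per_region, high_ros_proportion)
            low = low_mode * rng.lognormal(0.0, low_sigma, cells_per_region - n_high)
            high = high_multiplier * low_mode * rng.lognormal(0.0, low_sigma, n_high)
            for v in np.concatenate([low, high]):
                cells.append({"animal": animal, "region": region, "intensity": v})
            dapi.append(
                {"animal": animal, "region": region,
                 "dapi_total": cells_per_region + extra_unmeasured}
            )
    return CellIntensityTable(pd.DataFrame(cells), pd.DataFrame(dapi))


# ---------------------------------------------------------------------------
# ABTS / Trolox antioxidant capacity
# ---------------------------------------------------------------------------


@dataclass
class AntioxidantRun:
    """One ABTS oxidation run: sample absorbance at 734 nm versus time plus
    the Trolox standard lags. sample_lag_s, if None, is measured from the
    absorbance series."""

    time_s: np.ndarray
    absorbance: np.ndarray
    standards: list  # (trolox_concentration, lag_time_s) pairs
    sample_lag_s: Optional[float] = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.absorbance.shape:
            raise ParameterError("time and absorbance must be 1-D and equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ParameterError("time must be strictly increasing")
        concs = {c for c, _ in self.standards}
        if len(concs) < 2:
            raise ParameterError("need >= 2 distinct standard concentrations")


def measure_lag_time(
    time_s: np.ndarray, absorbance: np.ndarray, delta_frac: float = 0.1
) -> float:
    """Time at which absorbance first rises delta_frac of the total dynamic
    range above its initial plateau, by linear interpolation of the crossing."""
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    a0 = a[0]
    rise = float(a.max() - a0)
    if rise <= 0:
        raise ParameterError("absorbance never rises above its initial value")
    level = a0 + delta_frac * rise
    above = np.flatnonzero(a >= level)
    i = int(above[0])
    if i == 0:
        return float(t[0])
    # linear interpolation between the bracketing samples
    f = (level - a[i - 1]) / (a[i] - a[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


@dataclass
class CapacityResult:
    capacity: float  # Trolox-equivalent concentration
    sample_lag_s: float
    intercept: float
    slope: float
    extrapolated: bool


def antioxidant_capacity(run: AntioxidantRun, delta_frac: float = 0.1) -> CapacityResult:
    """Trolox-equivalent antioxidant capacity from a standard line.

    Fits lag = a + b * concentration to the standards by least squares and
    inverts it at the sample's lag time. A non-positive slope (lag not
    increasing with Trolox) is an error; a sample lag outside the standard
    lag range is flagged as extrapolated.
    """
    concs = np.array([c for c, _ in run.standards], dtype=float)
    lags = np.array([l for _, l in run.standards], dtype=float)
    b, a = np.polyfit(concs, lags, 1)
    if b <= 0:
        raise ParameterError("standard line slope must be positive")
    sample_lag = (
        run.sample_lag_s
        if run.sample_lag_s is not None
        else measure_lag_time(run.time_s, run.absorbance, delta_frac)
    )
    capacity = (sample_lag - a) / b
    extrapolated = not (lags.min() <= sample_lag <= lags.max())
    return CapacityResult(float(capacity), float(sample_lag), float(a), float(b), extrapolated)


def simulate_antioxidant_run(
    capacity_true: float,
    intercept_s: float = 30.0,
    slope_s_per_um: float = 0.6,
    standard_concs: Sequence[float] = (0.0, 50.0, 100.0, 200.0, 400.0),
    lag_noise_frac: float = 0.0,
    a0: float = 0.05,
    rise: float = 1.0,
    ramp_s: float = 30.0,
    dt_s: float = 2.0,
    delta_frac: float = 0.1,
    seed: int = 0,
) -> AntioxidantRun:
    """Generate a run whose measured sample lag is intercept + slope * capacity.

    The absorbance curve is a plateau followed by a linear rise positioned so
    the delta_frac threshold crossing lands exactly on the intended lag;
    lag_noise_frac adds proportional noise to the standard and sample lags.
    """
    rng = np.random.default_rng(seed)
    lag_true = intercept_s + slope_s_per_um * capacity_true
    if lag_noise_frac > 0:
        lag_true *= 1.0 + lag_noise_frac * rng.standard_normal()
    stds = []
    for c in standard_concs:
        lag = intercept_s + slope_s_per_um * c
        if lag_noise_frac > 0:
            lag *= 1.0 + lag_noise_frac * rng.standard_normal()
        stds.append((float(c), float(lag)))
    t_end = max(lag_true, max(l for _, l in stds)) + ramp_s + 60.0
    t = np.arange(0.0, t_end, dt_s)
    onset = lag_true - delta_frac * ramp_s  # threshold crossing == lag_true
    absorb = a0 + rise * np.clip((t - onset) / ramp_s, 0.0, 1.0)
    return AntioxidantRun(time_s=t, absorbance=absorb, standards=stds)


# ---------------------------------------------------------------------------
# 2^-ddCt relative quantification
# ---------------------------------------------------------------------------


@dataclass
class QPCRTable:
    """Per-sample threshold cycles for target genes and one reference gene.

    data: DataFrame with columns sample, group, gene, ct.
    reference_gene: normalizer present for every sample (e.g. 18S rRNA).
    """

    data: pd.DataFrame
    reference_gene: str = "18S"

    def __post_init__(self):
        for col in ("sample", "group", "gene", "ct"):
            if col not in self.data.columns:
                raise ParameterError(f"qPCR table missing column {col!r}")
        ct = self.data["ct"]
        if ((ct <= 0) | (ct > 40)).any():
            raise ParameterError("Ct values must lie in (0, 40]")
        samples = set(self.data["sample"])
        ref_samples = set(
            self.data.loc[self.data["gene"] == self.reference_gene, "sample"]
        )
        if samples - ref_samples:
            raise ParameterError(
                f"reference gene {self.reference_gene!r} missing for samples "
                f"{sorted(samples - ref_samples)}"
            )


def ddct_fold_change(table: QPCRTable, control_group: str) -> pd.DataFrame:
    """Per-sample ddCt and 2^-ddCt fold change for every target gene.

    dCt = Ct_gene - Ct_reference per sample; ddCt subtracts the control-group
    mean dCt, so the control group's *mean ddCt* is 0 and its geometric mean
    fold change is 1 by construction.
    """
    df = table.data
    if not (df["group"] == control_group).any():
        raise ParameterError(f"control group {control_group!r} not present")
    ref = (
        df[df["gene"] == table.reference_gene]
        .groupby("sample")["ct"]
        .mean()
        .rename("ct_ref")
    )
    targets = df[df["gene"] != table.reference_gene].copy()
    targets = targets.merge(ref, left_on="sample", right_index=True)
    targets["dct"] = targets["ct"] - targets["ct_ref"]
    out = []
    for gene, g in targets.groupby("gene"):
        ctrl = g.loc[g["group"] == control_group, "dct"]
        if ctrl.empty:
            raise ParameterError(f"no control samples for gene {gene!r}")
        ddct = g["dct"] - ctrl.mean()
        res = g[["sample", "group", "gene"]].copy()
        res["dct"] = g["dct"]
        res["ddct"] = ddct
        res["fold_change"] = np.power(2.0, -ddct)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def simulate_qpcr_table(
    genes_fold: dict | None = None,
    n_control: int = 8,
    n_treated: int = 8,
    reference_gene: str = "18S",
    ref_ct_mean: float = 18.0,
    base_dct: float = 8.0,
    ct_noise_sd: float = 0.0,
    control_group: str = "control",
    treated_group: str = "TBI",
    seed: int = 0,
) -> QPCRTable:
    """Generate Ct values with known true fold changes per target gene.

    genes_fold maps gene name to the treated-group expression fold change
    relative to control (fold f shifts the treated dCt by -log2(f)).
    Defaults emulate antioxidant-enzyme panels (SOD1, SOD2, catalase).
    """
    if genes_fold is None:
        genes_fold = {"SOD1": 0.5, "SOD2": 0.5, "catalase": 1.0}
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in ((control_group, n_control), (treated_group, n_treated)):
        for i in range(n):
            sample = f"{group}_{i+1}"
            ct_ref = ref_ct_mean + ct_noise_sd * rng.standard_normal()
            rows.append(
                {"sample": sample, "group": group, "gene": reference_gene, "ct": ct_ref}
            )
            for gene, fold in genes_fold.items():
                dct = base_dct + ct_noise_sd * rng.standard_normal()
                if group == treated_group:
                    dct -= np.log2(fold)
                rows.append(
                    {"sample": sample, "group": group, "gene": gene, "ct": ct_ref + dct}
                )
    return QPCRTable(pd.DataFrame(rows), reference_gene=reference_gene)
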