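"""From raw per-sweep records to pooled, normalized analysis tables.

Mirrors an automated patch-clamp workflow: cells are QC-filtered on
seal quality and current size, per-cell fractional inhibition is
computed against a baseline epoch with a time-matched vehicle rundown
correction and a full-block (saturating blocker) reference, and
per-cell points are pooled into a concentration–response table with
one concentration per cell. Gating analyses (conductance transform,
availability curves, midpoint shifts) and peak/persistent current
quantification live here too.

Sign convention: inward sodium currents are stored negative; all block
fractions are computed on magnitudes, which makes every normalization
scale-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curve_models import BoltzmannFit, Polarity

__all__ = [
    "analyze_plate",
    "availability_curve",
    "vehicle_decay_curve",
    "pulse_train_block_fractions",
    "apparent_ic50_by_holding",
    "QC_RM_MIN_MOHM",
    "QC_RS_MAX_MOHM",
    "QC_PEAK_MIN_PA",
    "CellQC",
    "GatingCurve",
    "ConcentrationResponseTable",
    "qc_filter",
    "fraction_inhibition",
    "pool_concentration_response",
    "conductance_transform",
    "current_density",
    "percent_block_from_densities",
    "v_half_shift",
    "measure_peak_and_persistent",
]

# Plate QC thresholds: membrane resistance above 500 MΩ, series
# resistance below 10 MΩ, and baseline current magnitude above 500 pA.
QC_RM_MIN_MOHM = 500.0
QC_RS_MAX_MOHM = 10.0
QC_PEAK_MIN_PA = 500.0


@dataclass(frozen=True)
class CellQC:
    """Per-cell quality metrics recorded at baseline."""

    cell_id: str
    rm_MOhm: float        # membrane (seal) resistance
    rs_MOhm: float        # series resistance
    cap_pF: float         # membrane capacitance
    baseline_peak_pA: float

    def __post_init__(self) -> None:
        if self.rm_MOhm <= 0 or self.rs_MOhm <= 0 or self.cap_pF <= 0:
            raise ValueError("QC metrics must be positive")


@dataclass
class GatingCurve:
    """(voltage, normalized fraction) points for one gating measurement."""

    voltages: np.ndarray
    fraction: np.ndarray
    kind: Polarity

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.kind = Polarity(self.kind)
        if self.voltages.shape != self.fraction.shape:
            raise ValueError("voltages and fraction must have equal length")
        if len(self.fraction) and abs(self.fraction.max() - 1.0) > 1e-9:
            raise ValueError("gating curve must be normalized to max 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voltage_mV": self.voltages,
                             "fraction": self.fraction,
                             "kind": self.kind.value})


@dataclass
class ConcentrationResponseTable:
    """Pooled concentration–response data with per-cell provenance.

    ``pooled`` has one row per concentration (mean inhibition and n);
    ``cells`` retains every per-cell point. The default Hill fit input
    is the per-concentration mean, matching pooled-mean fitting;
    per-cell fitting is available via ``cell_points``.
    """

    pooled: pd.DataFrame   # columns: conc_uM, inhibition_mean, n_cells
    cells: pd.DataFrame    # columns: cell_id, conc_uM, inhibition

    @property
    def concentrations(self) -> np.ndarray:
        return self.pooled["conc_uM"].to_numpy(dtype=float)

    @property
    def inhibition(self) -> np.ndarray:
        return self.pooled["inhibition_mean"].to_numpy(dtype=float)

    def cell_points(self):
        """(concentration, inhibition) arrays over all individual cells."""
        return (self.cells["conc_uM"].to_numpy(dtype=float),
                self.cells["inhibition"].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.pooled)


def qc_filter(cells) -> tuple[list, pd.DataFrame]:
    """Partition cells into included / excluded with labelled reasons.

    Exclusion rules: Rm ≤ 500 MΩ ("low Rm"), Rs ≥ 10 MΩ ("high Rs"),
    |baseline peak| ≤ 500 pA ("small current"). A cell may fail on
    several counts; every reason is recorded.

    Returns (included cells, exclusion DataFrame with cell_id/reason).
    """
    included, excluded = [], []
    for cell in cells:
        reasons = []
        if cell.rm_MOhm <= QC_RM_MIN_MOHM:
            reasons.append(f"low Rm ({cell.rm_MOhm:g} MΩ ≤ {QC_RM_MIN_MOHM:g})")
        if cell.rs_MOhm >= QC_RS_MAX_MOHM:
            reasons.append(f"high Rs ({cell.rs_MOhm:g} MΩ ≥ {QC_RS_MAX_MOHM:g})")
        if abs(cell.baseline_peak_pA) <= QC_PEAK_MIN_PA:
            reasons.append(f"small current (|{cell.baseline_peak_pA:g}| pA "
                           f"≤ {QC_PEAK_MIN_PA:g})")
        if reasons:
            excluded.append({"cell_id": cell.cell_id,
                             "reason": "; ".join(reasons)})
        else:
            included.append(cell)
    return included, pd.DataFrame(excluded, columns=["cell_id", "reason"])


def fraction_inhibition(baseline_pA: float, drug_pA: float,
                        full_block_pA: float,
                        vehicle_decay: float = 1.0, *,
                        clip: bool = True) -> float:
    """Fractional inhibition referenced to baseline and full block.

    ``vehicle_decay`` is the time-matched mean fraction of current
    remaining on vehicle wells (1.0 = no rundown); the expected
    compound-free current is ``baseline · vehicle_decay``. The result
    is clipped to [0, 1] unless ``clip=False`` (the pipeline pools
    unclipped per-cell values so that zero-inhibition wells average to
    zero instead of acquiring a positive clipping bias). Computed on
    magnitudes, so it is invariant to any overall current scale or
    sign convention.
    """
    b = abs(baseline_pA) * vehicle_decay
    d = abs(drug_pA)
    fb = abs(full_block_pA)
    if b <= fb:
        raise ValueError("baseline (after rundown correction) must exceed "
                         "the full-block reference in magnitude")
    frac = (b - d) / (b - fb)
    return float(np.clip(frac, 0.0, 1.0)) if clip else float(frac)


def pool_concentration_response(records: pd.DataFrame) -> ConcentrationResponseTable:
    """Pool per-cell inhibition points by concentration.

    ``records`` needs columns ``cell_id``, ``conc_uM``, ``inhibition``;
    each cell must carry exactly one concentration (single-exposure
    plate design). Output is sorted by concentration.
    """
    required = {"cell_id", "conc_uM", "inhibition"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records.empty:
        empty_pool = pd.DataFrame(columns=["conc_uM", "inhibition_mean", "n_cells"])
        return ConcentrationResponseTable(empty_pool, records.copy())

    per_cell = records.groupby("cell_id")["conc_uM"].nunique()
    bad = per_cell[per_cell > 1]
    if len(bad):
        raise ValueError("cells exposed to more than one concentration: "
                         f"{sorted(bad.index.tolist())}")

    cells = records[["cell_id", "conc_uM", "inhibition"]].copy()
    cells = cells.sort_values(["conc_uM", "cell_id"], kind="mergesort",
                              ignore_index=True)
    pooled = (cells.groupby("conc_uM", as_index=False)
              .agg(inhibition_mean=("inhibition", "mean"),
                   n_cells=("inhibition", "size"))
              .sort_values("conc_uM", ignore_index=True))
    return ConcentrationResponseTable(pooled, cells)


def conductance_transform(voltages_mV, peaks_pA, e_rev_mV: float) -> GatingCurve:
    """Convert a peak I/V family to a normalized activation curve.

    G(V) = I_peak(V) / (V − E_rev), normalized by its maximum. Points at
    the reversal potential are dropped with a warning (0/0).
    """
    v = np.asarray(voltages_mV, dtype=float)
    i = np.asarray(peaks_pA, dtype=float)
    keep = v != e_rev_mV
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} point(s) at the reversal "
                      f"potential {e_rev_mV} mV", stacklevel=2)
    v, i = v[keep], i[keep]
    g = i / (v - e_rev_mV)
    gmax = g.max()
    if gmax <= 0:
        raise ValueError("no positive conductance: all currents zero or "
                         "wrong sign for the given reversal potential")
    return GatingCurve(v, g / gmax, Polarity.ACTIVATION)


def current_density(peak_pA: float, capacitance_pF: float) -> float:
    """Capacitance-normalized current, pA/pF (signed)."""
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    return peak_pA / capacitance_pF


def percent_block_from_densities(vehicle_pA_per_pF: float,
                                 drug_pA_per_pF: float) -> float:
    """Percent of current lost in drug relative to vehicle: 100·(1 − d/v)."""
    if vehicle_pA_per_pF == 0:
        raise ValueError("vehicle current density must be non-zero")
    return 100.0 * (1.0 - abs(drug_pA_per_pF) / abs(vehicle_pA_per_pF))


def v_half_shift(fit_a: BoltzmannFit, fit_b: BoltzmannFit) -> float:
    """Signed midpoint shift (b − a), mV; negative = hyperpolarizing."""
    if fit_a.polarity is not fit_b.polarity:
        raise ValueError("cannot compare midpoints across polarities")
    return fit_b.v_half - fit_a.v_half


def measure_peak_and_persistent(t_ms, i_pA, *, peak_window_ms: float = 10.0,
                                persist_fraction: float = 0.1) -> tuple[float, float]:
    """Peak and persistent current from a depolarizing-step trace.

    Peak is the extremum (largest magnitude) within the first
    ``peak_window_ms``; persistent is the mean over the trailing
    ``persist_fraction`` of the step (default last 10% — the final
    10 ms of a 100-ms step).
    """
    t = np.asarray(t_ms, dtype=float)
    i = np.asarray(i_pA, dtype=float)
    if t.shape != i.shape or len(t) < 2:
        raise ValueError("trace must be two equal-length arrays of ≥2 samples")
    duration = t[-1] - t[0]
    if duration < 100.0:
        raise ValueError(f"step must last ≥100 ms, got {duration:g} ms")
    early = t - t[0] <= peak_window_ms
    if not early.any():
        raise ValueError("no samples inside the peak window")
    peak = float(i[early][np.argmax(np.abs(i[early]))])
    late = t - t[0] >= duration * (1.0 - persist_fraction)
    persistent = float(i[late].mean())
    return peak, persistent


def availability_curve(prepulse_mV, peaks_pA) -> GatingCurve:
    """Normalize SSFI test-pulse peaks into an availability curve.

    Magnitudes are divided by the largest peak (the most hyperpolarized
    prepulse for a healthy family).
    """
    v = np.asarray(prepulse_mV, dtype=float)
    i = np.abs(np.asarray(peaks_pA, dtype=float))
    imax = i.max()
    if imax <= 0:
        raise ValueError("all test-pulse currents are zero")
    return GatingCurve(v, i / imax, Polarity.AVAILABILITY)


def vehicle_decay_curve(sweeps: pd.DataFrame, *,
                        n_baseline_sweeps: int = 5):
    """Time-matched mean fractional current remaining on vehicle wells.

    Returns (times, decay) arrays over the drug epoch: for each vehicle
    cell the post-addition current is divided by that cell's own
    baseline (mean of the last ``n_baseline_sweeps`` pre-addition
    sweeps), then averaged across cells per time point. Linear
    interpolation between the points gives the correction at any
    measurement time.
    """
    veh_ids = sweeps.loc[(sweeps["epoch"] == "drug")
                         & (sweeps["conc_uM"] == 0), "cell_id"].unique()
    if len(veh_ids) == 0:
        return np.array([]), np.array([])
    ratios = []
    for cid in veh_ids:
        cell = sweeps[sweeps["cell_id"] == cid]
        base = cell[cell["epoch"] == "baseline"].nlargest(
            n_baseline_sweeps, "time_s")["peak_pA"].mean()
        drug = cell[cell["epoch"] == "drug"].sort_values("time_s")
        ratios.append(pd.Series((drug["peak_pA"] / base).to_numpy(),
                                index=drug["time_s"].to_numpy()))
    frame = pd.concat(ratios, axis=1)
    mean = frame.mean(axis=1)
    return mean.index.to_numpy(dtype=float), mean.to_numpy(dtype=float)


def analyze_plate(sweeps: pd.DataFrame, cells: pd.DataFrame, *,
                  n_baseline_sweeps: int = 5,
                  n_measure_sweeps: int = 5) -> dict:
    """Full plate reduction: QC, normalize, vehicle-correct, pool.

    Per QC-passing cell: baseline is the mean of the last
    ``n_baseline_sweeps`` pre-addition sweeps; the response is the mean
    of the last ``n_measure_sweeps`` drug-epoch sweeps (maximal
    inhibition at the end of exposure); the full-block epoch defines
    the zero-current reference, rescaled to the measurement time via
    the vehicle decay curve. Fractional inhibition then goes through
    :func:`fraction_inhibition` and is pooled by concentration.

    Returns a dict with the ``table`` (ConcentrationResponseTable over
    drug cells), ``per_cell`` rows for every passing cell including
    vehicle wells (conc_uM = 0), and the QC ``excluded`` frame.
    """
    qc_cells = [CellQC(r.cell_id, r.rm_MOhm, r.rs_MOhm, r.cap_pF,
                       r.baseline_peak_pA)
                for r in cells.itertuples(index=False)]
    included, excluded = qc_filter(qc_cells)
    keep_ids = {c.cell_id for c in included}

    dec_t, dec_f = vehicle_decay_curve(sweeps,
                                       n_baseline_sweeps=n_baseline_sweeps)

    def decay_at(t: float) -> float:
        if len(dec_t) == 0:
            return 1.0
        return float(np.interp(t, dec_t, dec_f))

    rows = []
    for cid, cell in sweeps.groupby("cell_id", sort=True):
        if cid not in keep_ids:
            continue
        base_rows = cell[cell["epoch"] == "baseline"]
        drug_rows = cell[cell["epoch"] == "drug"]
        fb_rows = cell[cell["epoch"] == "full_block"]
        if base_rows.empty or drug_rows.empty or fb_rows.empty:
            continue
        baseline = base_rows.nlargest(n_baseline_sweeps, "time_s")["peak_pA"].mean()
        meas = drug_rows.nlargest(n_measure_sweeps, "time_s")
        drug = meas["peak_pA"].mean()
        t_meas = meas["time_s"].mean()
        fb = fb_rows["peak_pA"].mean()
        t_fb = fb_rows["time_s"].mean()
        # rescale the (later) full-block reference to the measurement time
        d_fb = decay_at(t_fb)
        fb_matched = fb * (decay_at(t_meas) / d_fb if d_fb > 0 else 1.0)
        inh = fraction_inhibition(baseline, drug, fb_matched,
                                  vehicle_decay=decay_at(t_meas), clip=False)
        rows.append({"cell_id": cid,
                     "conc_uM": float(cell["conc_uM"].max()),
                     "inhibition": inh})
    per_cell = pd.DataFrame(rows, columns=["cell_id", "conc_uM", "inhibition"])
    # the fit table clips per-cell estimates into [0, 1] (the estimand is a
    # fraction); per_cell keeps raw values so vehicle wells average to zero
    fit_rows = per_cell[per_cell["conc_uM"] > 0].copy()
    fit_rows["inhibition"] = fit_rows["inhibition"].clip(0.0, 1.0)
    table = pool_concentration_response(fit_rows)
    return {"table": table, "per_cell": per_cell, "excluded": excluded}


def pulse_train_block_fractions(run: pd.DataFrame, *,
                                method: str = "plateau") -> pd.DataFrame:
    """Equilibrium fractional block per (holding potential, concentration).

    ``run`` is a pulse-train table (columns holding_mV, conc_uM, pulse,
    epoch, time_s, peak_pA). Per train, peaks are normalized to the
    pre-compound baseline pulses; the equilibrium block is either the
    plateau of a monoexponential fit to the relaxation (``"plateau"``,
    default — insensitive to truncated equilibration) or taken from the
    final pulse (``"last"``).
    """
    from .fitting import fit_monoexponential
    if method not in ("plateau", "last"):
        raise ValueError("method must be 'plateau' or 'last'")
    out = []
    for (vh, conc), grp in run.groupby(["holding_mV", "conc_uM"], sort=True):
        base = grp.loc[grp["epoch"] == "baseline", "peak_pA"].mean()
        drug = grp[grp["epoch"] == "drug"].sort_values("time_s")
        y = (drug["peak_pA"] / base).to_numpy(dtype=float)
        t = drug["time_s"].to_numpy(dtype=float)
        if method == "plateau":
            res = fit_monoexponential(t, y)
            final = res.params.plateau if res.converged else y[-1]
        else:
            final = y[-1]
        out.append({"holding_mV": vh, "conc_uM": conc,
                    "fraction_block": float(np.clip(1.0 - final, 0.0, 1.0))})
    return pd.DataFrame(out)


def apparent_ic50_by_holding(block: pd.DataFrame, *,
                             fix_slope=None) -> list[tuple[float, float]]:
    """Hill-fit apparent IC50 at each holding potential.

    ``block`` comes from :func:`pulse_train_block_fractions`. Returns
    [(holding_mV, IC50_uM), ...] sorted by holding potential — the
    input for the resting/inactivated state-model fit.
    """
    from .fitting import fit_hill
    points = []
    for vh, grp in block.groupby("holding_mV", sort=True):
        res = fit_hill(grp["conc_uM"].to_numpy(float),
                       grp["fraction_block"].to_numpy(float),
                       fix_slope=fix_slope)
        if not res.converged:
            raise ValueError(f"Hill fit failed at holding {vh} mV: "
                             f"{res.message}")
        points.append((float(vh), res.params.ic50))
    return points
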