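"""XIC extraction, peak integration and light/heavy quantification.

The quantification model is deliberately simple and transparent:

* every trace of a panel row is extracted from the run's targeted scans
  (matching the full selection path within a ppm tolerance at each level),
* trace intensities are integrated over retention time,
* traces of one combine group are summed into a single per-peptide area,
* relative mode normalizes areas to a reference peptide (the internal
  control, assigned an arbitrary intensity of 100),
* absolute mode converts the light/heavy area ratio of an analyte and its
  spiked isotope-labeled companion into fmol per 100 µg loaded protein:

      amount = (A_light / A_heavy) · spike_fmol · 100 / protein_µg

Spiked synthetic standards enter after digestion, so losses upstream of
the spike are not corrected for; results carry that caveat in metadata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .assay import AssayPanel, TraceDef, TransitionRow
from .config import QuantConfig

__all__ = [
    "Scan",
    "RunMetadata",
    "PRMRun",
    "XICTrace",
    "CombinedArea",
    "QuantResult",
    "extract_xic",
    "integrate",
    "combine_traces",
    "relative_quant",
    "absolute_quant",
    "replicate_stats",
    "detection_call",
    "quantify_run",
    "quantify_replicates",
    "results_frame",
]

QUANTIFIED = "quantified"
BELOW_LOQ = "detected_below_loq"
NOT_DETECTED = "not_detected"
NOT_QUANTIFIABLE = "not_quantifiable"


@dataclass(frozen=True)
class Scan:
    """One targeted scan: retention time (minutes), MS stage, the ordered
    isolation path (precursor, then MS3 selection if any) and a centroided
    peak list sorted by m/z."""

    rt: float
    stage: str  # MS2 | MS3
    selection_path: tuple[float, ...]
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < 0):
            raise ValueError("peaks must be sorted by m/z")


@dataclass(frozen=True)
class RunMetadata:
    run_id: str = ""
    sample_id: str = ""
    protein_ug: float | None = None
    spike_fmol: dict[str, float] = field(default_factory=dict)


@dataclass
class PRMRun:
    """Time-ordered targeted scans plus acquisition metadata."""

    scans: list[Scan]
    metadata: RunMetadata = field(default_factory=RunMetadata)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scans must be ordered by non-decreasing RT")


@dataclass(frozen=True)
class XICTrace:
    """Extracted ion chromatogram for one trace definition.  An empty
    ``points`` list means *no scan matched the selection path* — distinct
    from matching scans that contained no signal (intensity 0 points)."""

    trace: TraceDef
    points: tuple[tuple[float, float], ...]

    @property
    def rt(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def _ppm_match(value: float, target: float, tol_ppm: float) -> bool:
    return abs(value - target) <= target * tol_ppm * 1e-6


def extract_xic(
    run: PRMRun,
    trace: TraceDef,
    tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> XICTrace:
    """Extract one XIC: for every scan inside ``rt_window`` whose selection
    path matches the trace's path within ``tol_ppm`` at every level, emit
    (rt, summed intensity of peaks within ±tol_ppm of the monitored m/z).
    Matching scans without a matching peak contribute intensity 0."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    target = trace.monitored_mz
    half = target * tol_ppm * 1e-6
    points = []
    for scan in run.scans:
        if rt_window is not None and not rt_window[0] <= scan.rt <= rt_window[1]:
            continue
        if scan.stage != trace.stage:
            continue
        if len(scan.selection_path) != len(trace.selection_path):
            continue
        if not all(
            _ppm_match(s, t, tol_ppm)
            for s, t in zip(scan.selection_path, trace.selection_path)
        ):
            continue
        lo = np.searchsorted(scan.mz, target - half, side="left")
        hi = np.searchsorted(scan.mz, target + half, side="right")
        points.append((scan.rt, float(scan.intensity[lo:hi].sum())))
    return XICTrace(trace, tuple(points))


def integrate(xic: XICTrace, method: str = "trapezoid") -> float:
    """Integrate an XIC over retention time (minutes).

    ``trapezoid`` integrates the whole trace; ``peak`` restricts to the
    apex peak, bounded by the nearest local minima on either side (ties
    resolved toward the apex).  A single-point trace has zero width and
    integrates to 0 with a warning; an empty trace is rejected.
    """
    if not xic.points:
        raise ValueError("cannot integrate an empty XIC (no matching scans)")
    if len(xic.points) == 1:
        warnings.warn("single-point XIC integrates to zero area", stacklevel=2)
        return 0.0
    rt, inten = xic.rt, xic.intensity
    if method == "trapezoid":
        return float(np.trapezoid(inten, rt))
    if method == "peak":
        apex = int(np.argmax(inten))
        lo = apex
        while lo > 0 and inten[lo - 1] <= inten[lo]:
            lo -= 1
        hi = apex
        while hi < len(inten) - 1 and inten[hi + 1] <= inten[hi]:
            hi += 1
        if hi == lo:
            return 0.0
        return float(np.trapezoid(inten[lo : hi + 1], rt[lo : hi + 1]))
    raise ValueError(f"unknown integration method {method!r}")


@dataclass(frozen=True)
class CombinedArea:
    """Summed area of a combine group; ``complete`` is False when a member
    trace was missing from the input."""

    area: float
    n_traces: int
    complete: bool


def combine_traces(
    areas: dict[TraceDef, float], row: TransitionRow
) -> CombinedArea:
    """Sum member-trace areas of a panel row's combine group."""
    present = [areas[t] for t in row.traces if t in areas]
    if not present:
        raise ValueError(f"no trace areas supplied for {row.symbol!r}")
    return CombinedArea(
        area=float(sum(present)),
        n_traces=len(present),
        complete=len(present) == len(row.traces),
    )


def relative_quant(
    areas: dict[str, float], reference: str = "IC", scale: float = 100.0
) -> dict[str, float]:
    """Normalize per-symbol areas so the reference maps exactly to
    ``scale`` (the internal-control-equals-100 convention)."""
    if reference not in areas:
        raise ValueError(f"reference symbol {reference!r} missing from areas")
    ref = areas[reference]
    if ref <= 0:
        raise ValueError(f"reference area for {reference!r} is not positive")
    return {sym: scale * a / ref for sym, a in areas.items()}


def absolute_quant(
    light_area: float,
    heavy_area: float,
    spike_fmol: float,
    protein_ug: float,
) -> tuple[float | None, str]:
    """Isotope-dilution amount in fmol per 100 µg protein, plus a status.

    Returns ``(None, not_quantifiable)`` when the heavy standard gave no
    signal, and ``(0.0, not_detected)`` when the light area is zero.
    """
    if spike_fmol <= 0:
        raise ValueError("spike_fmol must be positive")
    if protein_ug <= 0:
        raise ValueError("protein_ug must be positive")
    if heavy_area <= 0:
        return None, NOT_QUANTIFIABLE
    if light_area <= 0:
        return 0.0, NOT_DETECTED
    amount = (light_area / heavy_area) * spike_fmol * (100.0 / protein_ug)
    return amount, QUANTIFIED


def replicate_stats(amounts: list[float]) -> tuple[float, float | None, float | None]:
    """Arithmetic mean, sample standard deviation (n-1) and CV percent.

    A single replicate yields a mean only; an empty list is rejected.
    """
    if not amounts:
        raise ValueError("no replicate values supplied")
    mean = float(np.mean(amounts))
    if len(amounts) < 2:
        return mean, None, None
    sd = float(np.std(amounts, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else math.inf
    return mean, sd, cv


def detection_call(
    light_area: float,
    light_heavy_ratio: float | None = None,
    noise_floor: float = 0.0,
    loq_ratio: float = 0.01,
) -> str:
    """Classify a signal: ``not_detected`` at or below the noise floor,
    ``detected_below_loq`` when present but with a light/heavy ratio under
    the quantification limit, else ``quantified``."""
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    if light_area <= noise_floor:
        return NOT_DETECTED
    if light_heavy_ratio is not None and light_heavy_ratio < loq_ratio:
        return BELOW_LOQ
    return QUANTIFIED


@dataclass(frozen=True)
class QuantResult:
    """Per-peptide outcome of one run."""

    run_id: str
    symbol: str
    area: float
    traces_complete: bool = True
    ratio_to_reference: float | None = None
    light_heavy_ratio: float | None = None
    amount_fmol_per_100ug: float | None = None
    status: str = QUANTIFIED
    note: str = ""


def _row_area(
    run: PRMRun, row: TransitionRow, cfg: QuantConfig
) -> CombinedArea | None:
    """Extract, integrate and combine all traces of one row; ``None`` when
    no scan in the run matched any of the row's selection paths."""
    areas: dict[TraceDef, float] = {}
    for t in row.traces:
        xic = extract_xic(run, t, cfg.tol_ppm, row.rt_window)
        if not xic.points:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            areas[t] = integrate(xic, cfg.integration)
    if not areas:
        return None
    return combine_traces(areas, row)


_LOSS_NOTE = "spiked after digestion; pre-spike losses not corrected"


def quantify_run(
    run: PRMRun, panel: AssayPanel, cfg: QuantConfig | None = None
) -> list[QuantResult]:
    """Quantify every light symbol of a panel in one run.

    Relative mode normalizes combined areas to the reference symbol;
    absolute mode requires run metadata (loaded protein, spike amounts)
    and each light row's heavy companion.
    """
    cfg = cfg or QuantConfig()
    combined: dict[str, CombinedArea] = {}
    for row in panel.rows:
        ca = _row_area(run, row, cfg)
        if ca is not None:
            combined[row.symbol] = ca
    if not combined:
        raise ValueError(
            f"run {run.metadata.run_id!r} contains no scans matching panel "
            f"{panel.name!r}"
        )
    results: list[QuantResult] = []
    if panel.mode == "relative":
        areas = {s: combined[s].area for s in panel.light_symbols if s in combined}
        ratios = relative_quant(areas, cfg.reference_symbol, cfg.reference_scale)
        for sym in panel.light_symbols:
            area = combined[sym].area if sym in combined else 0.0
            status = detection_call(area, None, cfg.noise_floor_area, cfg.loq_ratio)
            results.append(
                QuantResult(
                    run_id=run.metadata.run_id,
                    symbol=sym,
                    area=area,
                    traces_complete=sym in combined and combined[sym].complete,
                    ratio_to_reference=ratios.get(sym, 0.0),
                    status=status,
                )
            )
        return results
    # absolute mode
    meta = run.metadata
    if meta.protein_ug is None:
        raise ValueError("absolute quantification requires protein_ug in run metadata")
    for sym in panel.light_symbols:
        heavy_sym = panel.heavy_of(sym)
        if heavy_sym is None:
            raise ValueError(f"absolute panel row {sym!r} has no heavy companion")
        if heavy_sym not in meta.spike_fmol:
            raise ValueError(f"no spike amount recorded for {heavy_sym!r}")
        light = combined.get(sym)
        heavy = combined.get(heavy_sym)
        light_area = light.area if light is not None else 0.0
        heavy_area = heavy.area if heavy is not None else 0.0
        spike = meta.spike_fmol[heavy_sym]
        amount, status = absolute_quant(
            max(light_area, 0.0), heavy_area, spike, meta.protein_ug
        )
        ratio = light_area / heavy_area if heavy_area > 0 else None
        if status == QUANTIFIED:
            status = detection_call(
                light_area, ratio, cfg.noise_floor_area, cfg.loq_ratio
            )
            if status == NOT_DETECTED:
                amount = 0.0
        results.append(
            QuantResult(
                run_id=meta.run_id,
                symbol=sym,
                area=light_area,
                traces_complete=light is not None and light.complete,
                light_heavy_ratio=ratio,
                amount_fmol_per_100ug=amount,
                status=status,
                note=_LOSS_NOTE,
            )
        )
    return results


@dataclass(frozen=True)
class ReplicateSummary:
    symbol: str
    n: int
    replicate_mean: float
    replicate_sd: float | None
    cv_percent: float | None
    status: str


def quantify_replicates(
    runs: list[PRMRun], panel: AssayPanel, cfg: QuantConfig | None = None
) -> tuple[list[QuantResult], list[ReplicateSummary]]:
    """Quantify replicate runs and aggregate per symbol.

    The aggregated value is the amount (absolute mode) or the ratio to the
    reference (relative mode).  The aggregate status is the *best* call
    across replicates (quantified > below-LOQ > not detected), so a
    single missing replicate does not erase a detection.
    """
    cfg = cfg or QuantConfig()
    per_run = [quantify_run(run, panel, cfg) for run in runs]
    flat = [r for rs in per_run for r in rs]
    order = {QUANTIFIED: 0, BELOW_LOQ: 1, NOT_DETECTED: 2, NOT_QUANTIFIABLE: 3}
    summaries = []
    for sym in panel.light_symbols:
        group = [r for r in flat if r.symbol == sym]
        values = [
            (
                r.amount_fmol_per_100ug
                if panel.mode == "absolute"
                else r.ratio_to_reference
            )
            for r in group
        ]
        values = [v for v in values if v is not None]
        if not values:
            summaries.append(
                ReplicateSummary(sym, 0, math.nan, None, None, NOT_QUANTIFIABLE)
            )
            continue
        mean, sd, cv = replicate_stats(values)
        status = min((r.status for r in group), key=order.get)
        summaries.append(ReplicateSummary(sym, len(values), mean, sd, cv, status))
    return flat, summaries


def results_frame(results, summaries=None):
    """Results as a pandas DataFrame (written as TSV by the CLI)."""
    import pandas as pd

    df = pd.DataFrame([r.__dict__ for r in results])
    if summaries is not None:
        agg = pd.DataFrame([s.__dict__ for s in summaries])
        df = df.merge(agg, on="symbol", how="left", suffixes=("", "_replicate"))
    return df
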