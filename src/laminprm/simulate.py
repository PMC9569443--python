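"""Synthetic PRM runs with known ground truth.

The generator emulates a time-scheduled targeted acquisition: within each
panel row's retention-time window, scans are produced at a fixed cycle
time; the monitored ion of each trace receives a Gaussian elution profile

    I(t) = response · fmol_on_column · exp(-(t - apex)² / 2σ²) · (1 + ε),

with ε ~ Normal(0, cv) drawn per scan and trace, clipped at zero, plus a
configurable number of chemical-noise peaks drawn uniformly in m/z around
the monitored region with exponentially distributed intensities.  Light
and heavy isotopologues co-elute (same apex and width).  Zero-amount
analytes produce only noise.

Every run comes with a bookkeeping record: per trace, the summed intensity
that landed within the extraction tolerance of the monitored m/z in each
scan.  Extraction must recover these numbers point for point, which makes
the generator the integration oracle of the test suite.

Scenario fixtures mirror the study designs this assay was built for
(progeria versus control fibroblasts, patient versus donor white blood
cells, progeroid versus wild-type mice), with compressed chromatography so
a full design → simulate → quantify cycle stays fast.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .assay import AssayPanel, schedule
from .panels import build_panel
from .quant import PRMRun, RunMetadata, Scan

__all__ = [
    "GroundTruth",
    "simulate_run",
    "scenario_fixtures",
    "SCENARIO_NAMES",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator needs, and everything a test may assert.

    ``amounts`` maps light symbols to true analyte amounts (fmol per
    100 µg protein in absolute scenarios; arbitrary abundance units in
    relative ones).  ``spike_fmol`` maps heavy symbols to spiked standard
    amounts.  ``elution`` maps light symbols to (apex min, sigma min);
    heavy companions share their partner's profile.
    """

    amounts: dict[str, float]
    elution: dict[str, tuple[float, float]]
    spike_fmol: dict[str, float] = field(default_factory=dict)
    protein_ug: float = 100.0
    response_per_fmol: float = 2.0e4
    noise_cv: float = 0.05
    noise_peak_intensity: float = 30.0
    noise_peaks_per_trace: int = 5
    noise_mz_halfwidth: float = 2.0
    cycle_time_s: float = 1.0
    tol_ppm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sym, amt in self.amounts.items():
            if amt < 0:
                raise ValueError(f"negative amount for {sym!r}")
        for sym, amt in self.spike_fmol.items():
            if amt < 0:
                raise ValueError(f"negative spike for {sym!r}")


def _fmol_on_column(symbol: str, truth: GroundTruth, light_of: dict[str, str]) -> float:
    if symbol in light_of:  # heavy row: the spiked standard itself
        if symbol not in truth.spike_fmol:
            raise ValueError(f"no spike amount in ground truth for {symbol!r}")
        return truth.spike_fmol[symbol]
    if symbol not in truth.amounts:
        raise ValueError(f"no true amount in ground truth for {symbol!r}")
    return truth.amounts[symbol] * truth.protein_ug / 100.0


def simulate_run(
    panel: AssayPanel,
    truth: GroundTruth,
    *,
    run_id: str = "sim",
    sample_id: str = "",
) -> tuple[PRMRun, dict[tuple[str, int], list[tuple[float, float]]]]:
    """Generate one PRM run for a scheduled panel.

    Returns the run and the bookkeeping record mapping
    ``(symbol, trace index)`` to the per-scan (rt, intensity) values an
    extraction at ``truth.tol_ppm`` must reproduce exactly.  Identical
    seeds give identical runs.
    """
    rng = np.random.default_rng(truth.seed)
    light_of = {h: l for l, h in panel.heavy_pairs}
    step = truth.cycle_time_s / 60.0
    raw: list[tuple[float, int, int, Scan, list[tuple[int, float]]]] = []
    for row_idx, row in enumerate(panel.rows):
        if row.rt_window is None:
            raise ValueError(
                f"row {row.symbol!r} has no RT window; schedule the panel first"
            )
        fmol = _fmol_on_column(row.symbol, truth, light_of)
        apex, sigma = truth.elution[light_of.get(row.symbol, row.symbol)]
        start, end = row.rt_window
        n_cycles = int(math.floor((end - start) / step))
        times = start + step * np.arange(n_cycles)
        # group traces into scans: MS3 traces each have their own selection
        # path; MS2 traces of a row share one scan
        if row.traces and row.traces[0].stage == "MS3":
            scan_groups = [(t.selection_path, [ti]) for ti, t in enumerate(row.traces)]
        else:
            scan_groups = [(row.traces[0].selection_path, list(range(len(row.traces))))]
        for rt in times:
            profile = math.exp(-((rt - apex) ** 2) / (2.0 * sigma**2))
            for gi, (path, trace_idx) in enumerate(scan_groups):
                mzs: list[float] = []
                intens: list[float] = []
                for ti in trace_idx:
                    trace = row.traces[ti]
                    amp = truth.response_per_fmol * fmol * profile
                    if amp > 0.0:
                        eps = rng.normal(0.0, truth.noise_cv)
                        inten = max(amp * (1.0 + eps), 0.0)
                        mzs.append(trace.monitored_mz)
                        intens.append(inten)
                    n_noise = truth.noise_peaks_per_trace
                    if n_noise:
                        nmz = rng.uniform(
                            trace.monitored_mz - truth.noise_mz_halfwidth,
                            trace.monitored_mz + truth.noise_mz_halfwidth,
                            n_noise,
                        )
                        nint = rng.exponential(truth.noise_peak_intensity, n_noise)
                        mzs.extend(nmz.tolist())
                        intens.extend(nint.tolist())
                order = np.argsort(mzs, kind="stable")
                mz_arr = np.asarray(mzs, dtype=float)[order]
                in_arr = np.asarray(intens, dtype=float)[order]
                scan = Scan(float(rt), row.traces[0].stage, path, mz_arr, in_arr)
                book_entries = []
                for ti in trace_idx:
                    target = row.traces[ti].monitored_mz
                    half = target * truth.tol_ppm * 1e-6
                    lo = np.searchsorted(mz_arr, target - half, side="left")
                    hi = np.searchsorted(mz_arr, target + half, side="right")
                    book_entries.append((ti, float(in_arr[lo:hi].sum())))
                raw.append((float(rt), row_idx, gi, scan, book_entries))
    raw.sort(key=lambda item: (item[0], item[1], item[2]))
    scans = [item[3] for item in raw]
    bookkeeping: dict[tuple[str, int], list[tuple[float, float]]] = {}
    for rt, row_idx, _gi, _scan, entries in raw:
        sym = panel.rows[row_idx].symbol
        for ti, inten in entries:
            bookkeeping.setdefault((sym, ti), []).append((rt, inten))
    meta = RunMetadata(
        run_id=run_id,
        sample_id=sample_id,
        protein_ug=truth.protein_ug,
        spike_fmol=dict(truth.spike_fmol),
    )
    return PRMRun(scans, meta), bookkeeping


# ---------------------------------------------------------------------------
# scenario fixtures

#: compressed chromatography used for simulation: windows (min) and
#: elution (apex, sigma) per light symbol.  Real acquisitions spread the
#: same targets over a multi-hour gradient; nothing downstream depends on
#: the absolute time scale.
_SIM_WINDOWS = {"IC": (0.0, 4.0), "LA": (4.0, 8.0), "FP": (8.0, 14.0)}
_SIM_ELUTION = {"IC": (2.0, 0.08), "LA": (6.0, 0.08), "FP": (11.0, 0.08)}

_HUMAN_SPIKES = {"IC*": 100.0, "LA*": 100.0, "hFP*": 50.0}

#: scenario truths.  Absolute human amounts follow the reported study
#: conditions: progeria fibroblasts carry ~43 fmol progerin and ~133 fmol
#: lamin A per 100 µg protein versus ~224 fmol lamin A in controls; the
#: control channel sees the sum of all proteoforms.  Patient white blood
#: cells carry progerin above detection but below the quantification
#: limit.  Mouse scenarios encode the LA/IC abundance patterns (≈1 in
#: wild type, ≈1/3 in the progeroid knock-in).
_SCENARIOS: dict[str, dict] = {
    "hgps_fibroblasts": {
        "panel": "human_absolute",
        "amounts": {"IC": 176.0, "LA": 133.0, "hFP": 43.0},
        "spikes": _HUMAN_SPIKES,
    },
    "control_fibroblasts": {
        "panel": "human_absolute",
        "amounts": {"IC": 224.0, "LA": 224.0, "hFP": 0.0},
        "spikes": _HUMAN_SPIKES,
    },
    "wbc_patient": {
        "panel": "human_absolute",
        "amounts": {"IC": 120.0, "LA": 100.0, "hFP": 0.4},
        "spikes": _HUMAN_SPIKES,
    },
    "wbc_donor": {
        "panel": "human_absolute",
        "amounts": {"IC": 140.0, "LA": 120.0, "hFP": 0.0},
        "spikes": _HUMAN_SPIKES,
    },
    "mouse_g609g": {
        "panel": "mouse_relative",
        "amounts": {"IC": 100.0, "LA": 100.0 / 3.0, "mFP": 30.0},
        "spikes": {},
    },
    "mouse_wt": {
        "panel": "mouse_relative",
        "amounts": {"IC": 100.0, "LA": 100.0, "mFP": 0.0},
        "spikes": {},
    },
}

SCENARIO_NAMES = tuple(sorted(_SCENARIOS))


def scenario_fixtures(name: str, seed: int = 0) -> tuple[AssayPanel, GroundTruth]:
    """Return (scheduled panel, ground truth) for a named study scenario."""
    try:
        spec = _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        ) from None
    panel = build_panel(spec["panel"])
    fp = "mFP" if spec["panel"] == "mouse_relative" else "hFP"
    windows = {
        "IC": _SIM_WINDOWS["IC"],
        "LA": _SIM_WINDOWS["LA"],
        fp: _SIM_WINDOWS["FP"],
    }
    panel = schedule(panel, windows)
    elution = {
        "IC": _SIM_ELUTION["IC"],
        "LA": _SIM_ELUTION["LA"],
        fp: _SIM_ELUTION["FP"],
    }
    truth = GroundTruth(
        amounts=dict(spec["amounts"]),
        elution=elution,
        spike_fmol=dict(spec["spikes"]),
        seed=seed,
    )
    return panel, truth


def replicate_truths(truth: GroundTruth, n: int, seed: int) -> list[GroundTruth]:
    """Derive ``n`` replicate truths differing only in their noise seed."""
    return [replace(truth, seed=seed + i) for i in range(n)]


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground-truth sidecar (structured text, consumed by tests
    and the CLI log, never by the quantification path)."""
    d = {
        "amounts": truth.amounts,
        "spike_fmol": truth.spike_fmol,
        "protein_ug": truth.protein_ug,
        "elution": {k: list(v) for k, v in truth.elution.items()},
        "response_per_fmol": truth.response_per_fmol,
        "noise_cv": truth.noise_cv,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
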