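"""Executable PRM transition tables: precursor targets, MS3 selections,
XIC trace definitions, heavy companions and retention-time scheduling.

A panel row is one peptide target: its precursor ion, and a small set of
trace definitions saying which ion is monitored on which acquisition path.
Two acquisition patterns are supported:

* **MS3**: the precursor is isolated, one intense fragment (or the
  farnesyl neutral-loss ion) is selected for a further round of
  fragmentation, and one of its products is monitored.  The selection path
  has two m/z levels.
* **MS2 XIC**: fragments are monitored directly in the precursor's MS2
  spectra; the selection path has one level.

Traces sharing a ``combine_group`` are summed into one quantitative signal
per peptide.  Every m/z in a trace is computed by :mod:`laminprm.chem`
from the peptide definition — no free-typed numbers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .chem import (
    DEFAULT_REGISTRY,
    HeavyLabelSpec,
    Modification,
    ModificationRegistry,
    ModifiedPeptide,
    apply_heavy_label,
    fragment_mz,
    neutral_loss_mz,
    precursor_mz,
    table_mz,
)

__all__ = [
    "IonSpec",
    "TraceSpec",
    "TraceScheme",
    "TraceDef",
    "TransitionRow",
    "AssayPanel",
    "design_transitions",
    "add_heavy_companions",
    "schedule",
    "write_transition_csv",
    "read_transition_csv",
]


_ION_RE = re.compile(r"^(precursor|NL-H2O|NL|([by])(\d+))(?:\((\d+)\+\))?$")


@dataclass(frozen=True)
class IonSpec:
    """Symbolic ion description, resolvable to m/z for any peptide.

    ``kind`` is ``precursor``, ``b``, ``y``, ``NL`` (farnesyl neutral loss
    of the precursor) or ``NL-H2O`` (the same after water loss).
    ``defarnesylated`` computes b/y fragments on the farnesyl-stripped,
    still O-methylated species (what MS3 sees after the neutral loss).
    """

    kind: str
    index: int | None = None
    charge: int = 1
    defarnesylated: bool = False

    def mz(self, peptide: ModifiedPeptide) -> float:
        if self.kind == "precursor":
            return precursor_mz(peptide, self.charge)
        if self.kind in ("NL", "NL-H2O"):
            if not peptide.is_farnesylated:
                raise ValueError(
                    f"{self.kind} requires a farnesylated peptide "
                    f"({peptide.symbol or peptide.sequence})"
                )
            mz = neutral_loss_mz(
                precursor_mz(peptide, self.charge), self.charge, "farnesyl"
            )
            if self.kind == "NL-H2O":
                mz = neutral_loss_mz(mz, self.charge, "water")
            return mz
        return fragment_mz(
            peptide,
            self.kind,
            self.index,
            self.charge,
            defarnesylated=self.defarnesylated,
        )

    @property
    def label(self) -> str:
        head = self.kind if self.index is None else f"{self.kind}{self.index}"
        return head if self.charge == 1 else f"{head}({self.charge}+)"

    @classmethod
    def parse(cls, label: str, defarnesylated: bool = False) -> "IonSpec":
        m = _ION_RE.match(label.strip())
        if not m:
            raise ValueError(f"cannot parse ion label {label!r}")
        full, series, idx, z = m.groups()
        charge = int(z) if z else 1
        if series:
            return cls(series, int(idx), charge, defarnesylated)
        return cls(full, None, charge, defarnesylated)


@dataclass(frozen=True)
class TraceSpec:
    """One trace of a design strategy: the acquisition stage, the MS3
    selection ion (``None`` for MS2 XIC traces) and the monitored ion."""

    stage: str  # MS2 | MS3
    monitored: IonSpec
    selection: IonSpec | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("MS2", "MS3"):
            raise ValueError(f"stage must be MS2 or MS3, got {self.stage!r}")
        if (self.stage == "MS3") != (self.selection is not None):
            raise ValueError("MS3 traces require a selection ion; MS2 traces none")


@dataclass(frozen=True)
class TraceScheme:
    """A full per-peptide design strategy: precursor charge + traces."""

    precursor_charge: int
    traces: tuple[TraceSpec, ...]


@dataclass(frozen=True)
class TraceDef:
    """A concrete XIC trace: the selection path (precursor m/z, then the
    MS3 selection m/z if any) and the monitored m/z, with its symbolic
    labels retained so the trace can be re-derived for a labeled peptide."""

    stage: str
    selection_path: tuple[float, ...]
    monitored_mz: float
    ion_label: str
    combine_group: str
    selection_label: str = ""
    defarnesylated: bool = False

    def __post_init__(self) -> None:
        expected = 2 if self.stage == "MS3" else 1
        if len(self.selection_path) != expected:
            raise ValueError(
                f"{self.stage} trace needs a {expected}-element selection path"
            )

    def spec(self) -> TraceSpec:
        sel = (
            IonSpec.parse(self.selection_label)
            if self.stage == "MS3"
            else None
        )
        return TraceSpec(
            self.stage, IonSpec.parse(self.ion_label, self.defarnesylated), sel
        )


@dataclass(frozen=True)
class TransitionRow:
    """One panel entry: a peptide target with its traces and RT window."""

    symbol: str
    peptide: ModifiedPeptide
    precursor_mz: float
    precursor_z: int
    traces: tuple[TraceDef, ...]
    rt_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rt_window is not None and not self.rt_window[0] < self.rt_window[1]:
            raise ValueError(f"rt_window start must precede end: {self.rt_window}")

    def scheme(self) -> TraceScheme:
        return TraceScheme(self.precursor_z, tuple(t.spec() for t in self.traces))


@dataclass(frozen=True)
class AssayPanel:
    name: str
    rows: tuple[TransitionRow, ...]
    mode: str = "relative"  # relative | absolute
    heavy_pairs: tuple[tuple[str, str], ...] = ()  # (light, heavy) symbols

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValueError(f"mode must be relative or absolute, got {self.mode!r}")
        symbols = [r.symbol for r in self.rows]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate symbols in panel")
        for light, heavy in self.heavy_pairs:
            if light not in symbols or heavy not in symbols:
                raise ValueError(f"heavy pair ({light}, {heavy}) not in panel")

    def row(self, symbol: str) -> TransitionRow:
        for r in self.rows:
            if r.symbol == symbol:
                return r
        raise KeyError(f"no row for symbol {symbol!r}")

    @property
    def symbols(self) -> list[str]:
        return [r.symbol for r in self.rows]

    @property
    def light_symbols(self) -> list[str]:
        heavy = {h for _, h in self.heavy_pairs}
        return [s for s in self.symbols if s not in heavy]

    def heavy_of(self, light: str) -> str | None:
        return dict(self.heavy_pairs).get(light)


def _auto_scheme(peptide: ModifiedPeptide) -> TraceScheme:
    """Fallback strategy when no published trace choice exists: MS2 XIC of
    two informative ions — for farnesylated peptides the neutral-loss ion
    plus a long defarnesylated b ion, otherwise two long y ions."""
    n = len(peptide.sequence)
    if n < 4:
        raise ValueError(f"peptide {peptide.sequence!r} too short for a transition")
    if peptide.is_farnesylated:
        traces = (
            TraceSpec("MS2", IonSpec("NL", None, 1)),
            TraceSpec("MS2", IonSpec("b", n - 2, 1, defarnesylated=True)),
        )
    else:
        traces = (
            TraceSpec("MS2", IonSpec("y", n - 2, 1)),
            TraceSpec("MS2", IonSpec("y", max(2, n // 2), 1)),
        )
    return TraceScheme(2, traces)


def design_transitions(
    peptide: ModifiedPeptide,
    strategy: TraceScheme | str = "auto",
    *,
    symbol: str | None = None,
) -> TransitionRow:
    """Turn a peptide plus a design strategy into a concrete panel row.

    ``strategy`` is either an explicit :class:`TraceScheme` (used for the
    published panels, whose fragment choices are fixed data) or ``"auto"``.
    All m/z values are computed from the peptide; requesting a fragment
    index outside the peptide is rejected by the mass calculus.
    """
    scheme = _auto_scheme(peptide) if strategy == "auto" else strategy
    sym = symbol if symbol is not None else peptide.symbol
    prec = precursor_mz(peptide, scheme.precursor_charge)
    traces = []
    for ts in scheme.traces:
        if ts.stage == "MS3":
            path = (prec, ts.selection.mz(peptide))
            sel_label = ts.selection.label
        else:
            path = (prec,)
            sel_label = ""
        traces.append(
            TraceDef(
                stage=ts.stage,
                selection_path=path,
                monitored_mz=ts.monitored.mz(peptide),
                ion_label=ts.monitored.label,
                combine_group=sym,
                selection_label=sel_label,
                defarnesylated=ts.monitored.defarnesylated,
            )
        )
    return TransitionRow(
        symbol=sym,
        peptide=peptide,
        precursor_mz=prec,
        precursor_z=scheme.precursor_charge,
        traces=tuple(traces),
    )


def add_heavy_companions(
    panel: AssayPanel, labels: dict[str, HeavyLabelSpec]
) -> AssayPanel:
    """Add an isotope-labeled companion row per labeled symbol.

    The heavy row re-derives every trace on the labeled peptide, so the
    precursor always shifts by label delta over charge while a fragment
    shifts only when it contains the labeled residue; a monitored fragment
    that does not contain it is still emitted, unshifted, with a warning.
    """
    for sym in labels:
        panel.row(sym)  # raises for unknown symbols
    rows = list(panel.rows)
    pairs = list(panel.heavy_pairs)
    for sym, spec in labels.items():
        light = panel.row(sym)
        heavy_pep = apply_heavy_label(light.peptide, spec)
        heavy = design_transitions(heavy_pep, light.scheme(), symbol=sym + "*")
        if spec.delta > 0:
            for lt, ht in zip(light.traces, heavy.traces):
                if ht.monitored_mz == lt.monitored_mz:
                    warnings.warn(
                        f"{heavy.symbol}: monitored ion {ht.ion_label} does not "
                        "contain the labeled residue; trace emitted unshifted",
                        stacklevel=2,
                    )
        heavy = replace(heavy, rt_window=light.rt_window)
        rows.append(heavy)
        pairs.append((sym, heavy.symbol))
    return AssayPanel(panel.name, tuple(rows), mode="absolute", heavy_pairs=tuple(pairs))


def schedule(
    panel: AssayPanel, windows: dict[str, tuple[float, float]]
) -> AssayPanel:
    """Attach retention-time windows; a heavy row shares its light
    partner's window.  Missing windows are rejected."""
    light_of = {h: l for l, h in panel.heavy_pairs}
    rows = []
    for row in panel.rows:
        key = row.symbol if row.symbol in windows else light_of.get(row.symbol)
        if key is None or key not in windows:
            raise ValueError(f"no RT window supplied for {row.symbol!r}")
        rows.append(replace(row, rt_window=tuple(windows[key])))
    return AssayPanel(panel.name, tuple(rows), panel.mode, panel.heavy_pairs)


# ---------------------------------------------------------------------------
# CSV serialization

_COLUMNS = [
    "panel_name",
    "panel_mode",
    "symbol",
    "sequence",
    "mods",
    "label",
    "z",
    "precursor_mz",
    "precursor_mz_display",
    "stage",
    "selection_label",
    "selection_path",
    "monitored_mz",
    "monitored_mz_display",
    "ion_label",
    "defarnesylated",
    "combine_group",
    "rt_start",
    "rt_end",
]


def _fmt_mods(p: ModifiedPeptide) -> str:
    return ";".join(f"{pos}:{mod.name}" for pos, mod in p.mods)


def _parse_mods(
    s: str, registry: ModificationRegistry
) -> tuple[tuple[int, Modification], ...]:
    if not s:
        return ()
    out = []
    for item in s.split(";"):
        pos, name = item.split(":")
        out.append((int(pos), registry[name]))
    return tuple(out)


def _fmt_label(spec: HeavyLabelSpec | None) -> str:
    if spec is None:
        return ""
    return f"{spec.residue_position}:{spec.n_13c}C{spec.n_15n}N"


_LABEL_RE = re.compile(r"^(.+):(\d+)C(\d+)N$")


def _parse_label(s: str) -> HeavyLabelSpec | None:
    if not s:
        return None
    m = _LABEL_RE.match(s)
    if not m:
        raise ValueError(f"cannot parse heavy-label spec {s!r}")
    pos = m.group(1)
    if pos not in ("N-term", "C-term"):
        pos = int(pos)
    return HeavyLabelSpec(pos, int(m.group(2)), int(m.group(3)))


def write_transition_csv(panel: AssayPanel, dest) -> None:
    """Write one CSV line per trace; m/z at full precision plus 4-decimal
    display columns.  Comma-separated, UTF-8, '.' decimal separator."""
    records = []
    for row in panel.rows:
        for t in row.traces:
            records.append(
                {
                    "panel_name": panel.name,
                    "panel_mode": panel.mode,
                    "symbol": row.symbol,
                    "sequence": row.peptide.sequence,
                    "mods": _fmt_mods(row.peptide),
                    "label": _fmt_label(row.peptide.label),
                    "z": row.precursor_z,
                    "precursor_mz": repr(row.precursor_mz),
                    "precursor_mz_display": f"{table_mz(row.precursor_mz):.4f}",
                    "stage": t.stage,
                    "selection_label": t.selection_label,
                    "selection_path": "|".join(repr(x) for x in t.selection_path),
                    "monitored_mz": repr(t.monitored_mz),
                    "monitored_mz_display": f"{table_mz(t.monitored_mz):.4f}",
                    "ion_label": t.ion_label,
                    "defarnesylated": int(t.defarnesylated),
                    "combine_group": t.combine_group,
                    "rt_start": "" if row.rt_window is None else repr(row.rt_window[0]),
                    "rt_end": "" if row.rt_window is None else repr(row.rt_window[1]),
                }
            )
    pd.DataFrame.from_records(records, columns=_COLUMNS).to_csv(
        dest, index=False, encoding="utf-8"
    )


def read_transition_csv(
    src, registry: ModificationRegistry = DEFAULT_REGISTRY
) -> AssayPanel:
    """Read a transition CSV back into an :class:`AssayPanel`.

    Raises ``ValueError`` naming the offending CSV line on malformed rows.
    Round-trips :func:`write_transition_csv` exactly.
    """
    df = pd.read_csv(src, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transition CSV is missing columns: {missing}")
    if len(df) == 0:
        return AssayPanel("empty", ())
    rows: dict[str, dict] = {}
    order: list[str] = []
    panel_name = df.iloc[0]["panel_name"]
    panel_mode = df.iloc[0]["panel_mode"]
    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            sym = rec["symbol"]
            if sym not in rows:
                peptide = ModifiedPeptide(
                    rec["sequence"],
                    _parse_mods(rec["mods"], registry),
                    _parse_label(rec["label"]),
                    symbol=sym,
                )
                rt = (
                    (float(rec["rt_start"]), float(rec["rt_end"]))
                    if rec["rt_start"]
                    else None
                )
                rows[sym] = {
                    "peptide": peptide,
                    "z": int(rec["z"]),
                    "precursor_mz": float(rec["precursor_mz"]),
                    "rt_window": rt,
                    "traces": [],
                }
                order.append(sym)
            path = tuple(float(x) for x in rec["selection_path"].split("|"))
            rows[sym]["traces"].append(
                TraceDef(
                    stage=rec["stage"],
                    selection_path=path,
                    monitored_mz=float(rec["monitored_mz"]),
                    ion_label=rec["ion_label"],
                    combine_group=rec["combine_group"],
                    selection_label=rec["selection_label"],
                    defarnesylated=bool(int(rec["defarnesylated"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed transition CSV at line {line}: {exc}") from exc
    built = tuple(
        TransitionRow(
            symbol=sym,
            peptide=rows[sym]["peptide"],
            precursor_mz=rows[sym]["precursor_mz"],
            precursor_z=rows[sym]["z"],
            traces=tuple(rows[sym]["traces"]),
            rt_window=rows[sym]["rt_window"],
        )
        for sym in order
    )
    symbols = set(order)
    pairs = tuple(
        (s, s + "*") for s in order if not s.endswith("*") and s + "*" in symbols
    )
    return AssayPanel(panel_name, built, panel_mode, pairs)
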