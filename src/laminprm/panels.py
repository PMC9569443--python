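"""The published lamin A / progerin PRM panels, regenerated from sequence.

Three panels are provided:

* ``mouse_relative`` — MS3 assay for the relative quantification of lamin A
  and progerin in Lmna G609G mouse samples (targets IC, LA, mFP).
* ``human_relative`` — time-scheduled MS3 assay for human samples
  (IC, LA, hFP).
* ``human_absolute`` — time-scheduled MS2-XIC assay with isotope-labeled
  companion peptides for stable-isotope-dilution absolute quantification
  (IC/IC*, LA/LA*, hFP/hFP*).

Panel construction is end-to-end: the bundled prelamin A sequence is
processed into proteoforms, digested, signature peptides are selected, and
transitions are designed.  The *fragment choices* (which y/b ions, which
neutral-loss paths) are fixed assay data — there is no physical rule that
derives them, so they are recorded here per peptide, and every m/z is then
computed from the peptide definition.
"""

from __future__ import annotations

from .assay import (
    AssayPanel,
    IonSpec,
    TraceScheme,
    TraceSpec,
    add_heavy_companions,
    design_transitions,
    schedule,
)
from .chem import HeavyLabelSpec, ModifiedPeptide
from .proteoforms import (
    FARN_PRELAMIN,
    MATURE,
    OBSERVABLE_PROTEOFORMS,
    PROGERIN,
    SurrogatePolicy,
    assign_signatures,
    build_proteoforms,
    bundled_sequence,
    select_surrogates,
)

__all__ = ["PANEL_NAMES", "build_panel", "select_panel_peptides", "HEAVY_LABELS"]

PANEL_NAMES = ("mouse_relative", "human_relative", "human_absolute")


def _ms3(selection: str, monitored: str, defarn: bool = False) -> TraceSpec:
    return TraceSpec(
        "MS3",
        IonSpec.parse(monitored, defarnesylated=defarn),
        IonSpec.parse(selection),
    )


def _ms2(monitored: str, defarn: bool = False) -> TraceSpec:
    return TraceSpec("MS2", IonSpec.parse(monitored, defarnesylated=defarn))


#: published per-peptide trace choices.  MS3 entries read
#: "selection > monitored"; fragments monitored downstream of the farnesyl
#: neutral loss are computed on the defarnesylated, O-methylated species.
TRACE_SCHEMES: dict[str, dict[str, TraceScheme]] = {
    "ms3_relative": {
        "IC": TraceScheme(2, (_ms3("y4", "y3"), _ms3("y11(2+)", "y9"))),
        "LA": TraceScheme(2, (_ms3("y15(2+)", "y7"), _ms3("y7", "y5"))),
        "mFP": TraceScheme(
            2, (_ms3("NL(2+)", "b11", True), _ms3("NL", "y11", True))
        ),
        "hFP": TraceScheme(
            2, (_ms3("NL(2+)", "b9", True), _ms3("NL", "NL-H2O"))
        ),
    },
    "ms2_absolute": {
        "IC": TraceScheme(2, (_ms2("y9"), _ms2("y11(2+)"))),
        "LA": TraceScheme(2, (_ms2("y15(2+)"), _ms2("y8"))),
        "hFP": TraceScheme(2, (_ms2("NL"), _ms2("b12", True))),
    },
}

#: isotope labels of the synthetic companion peptides: C-terminal Lys
#: (6x13C + 2x15N), C-terminal Arg (6x13C + 4x15N), N-terminal Ala
#: (3x13C + 1x15N).
HEAVY_LABELS: dict[str, HeavyLabelSpec] = {
    "IC": HeavyLabelSpec("C-term", 6, 2),
    "LA": HeavyLabelSpec("C-term", 6, 4),
    "hFP": HeavyLabelSpec("N-term", 3, 1),
}

#: retention-time schedules (minutes) of the time-scheduled human assays
RT_SCHEDULES: dict[str, dict[str, tuple[float, float]]] = {
    "human_relative": {"IC": (0, 70), "LA": (0, 70), "hFP": (70, 162)},
    "human_absolute": {"IC": (0, 35), "LA": (35, 70), "hFP": (70, 162)},
}

_ORGANISM = {
    "mouse_relative": ("P48678", "mouse"),
    "human_relative": ("P02545", "human"),
    "human_absolute": ("P02545", "human"),
}


def select_panel_peptides(
    accession: str, organism: str
) -> dict[str, ModifiedPeptide]:
    """Run the proteoform pipeline for a bundled sequence and name the
    selected surrogates with their conventional panel symbols.

    Symbols: IC (control, common to all proteoforms), LA (mature lamin A,
    falls in the progeria deletion), pre-LA (unmodified peptide unique to
    farnesylated prelamin A), zFP (farnesyl C-terminal peptide of wild-type
    farnesylated prelamin A), and mFP/hFP (the farnesyl C-terminal junction
    peptide of mouse/human progerin).
    """
    seq, deletion = bundled_sequence(accession)
    proteoforms = build_proteoforms(seq, deletion)
    observable = {n: proteoforms[n] for n in OBSERVABLE_PROTEOFORMS}
    assignments = assign_signatures(observable)
    of_interest = (
        (MATURE, FARN_PRELAMIN, PROGERIN) if organism == "mouse" else (MATURE, PROGERIN)
    )
    selected = select_surrogates(assignments, SurrogatePolicy(of_interest))
    fp_symbol = "mFP" if organism == "mouse" else "hFP"
    out: dict[str, ModifiedPeptide] = {}
    for role, picks in selected.items():
        for a in picks:
            pep = a.peptide
            if role == "control":
                sym = "IC"
            elif role == MATURE:
                sym = "LA"
            elif role == PROGERIN:
                sym = fp_symbol
            elif role == FARN_PRELAMIN:
                sym = "zFP" if pep.mods else "pre-LA"
            else:  # pragma: no cover - of_interest is fixed above
                sym = role
            out[sym] = ModifiedPeptide(pep.sequence, pep.mods, pep.label, symbol=sym)
    return out


def _with_cam(p: ModifiedPeptide) -> ModifiedPeptide:
    """Add carbamidomethyl to every Cys without a terminal lipid (samples
    are alkylated before digestion)."""
    from .chem import DEFAULT_REGISTRY

    cam = DEFAULT_REGISTRY["carbamidomethyl"]
    occupied = {pos for pos, _ in p.mods}
    extra = tuple(
        (i, cam)
        for i, res in enumerate(p.sequence, start=1)
        if res == "C" and i not in occupied
    )
    return ModifiedPeptide(p.sequence, p.mods + extra, p.label, p.symbol)


def build_panel(name: str) -> AssayPanel:
    """Build one of the published panels from the bundled sequences."""
    if name not in PANEL_NAMES:
        raise ValueError(f"unknown panel {name!r}; choose from {PANEL_NAMES}")
    accession, organism = _ORGANISM[name]
    peptides = select_panel_peptides(accession, organism)
    schemes = TRACE_SCHEMES[
        "ms2_absolute" if name == "human_absolute" else "ms3_relative"
    ]
    symbols = (
        ("IC", "LA", "mFP") if organism == "mouse" else ("IC", "LA", "hFP")
    )
    rows = tuple(
        design_transitions(_with_cam(peptides[sym]), schemes[sym]) for sym in symbols
    )
    panel = AssayPanel(name, rows, mode="relative")
    if name in RT_SCHEDULES:
        panel = schedule(panel, RT_SCHEDULES[name])
    if name == "human_absolute":
        panel = add_heavy_companions(panel, HEAVY_LABELS)
    return panel
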