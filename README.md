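# laminprm

Proteoform-resolved targeted proteomics for lamin A and farnesylated
progerin: assay design, synthetic PRM runs, and light/heavy quantification.

## The problem

Hutchinson–Gilford progeria syndrome (HGPS) is driven by progerin, a lamin A
variant that loses a 50-residue stretch containing the Zmpste24 cleavage
site and therefore stays permanently farnesylated and carboxymethylated.
The progerin-to-lamin-A ratio tracks disease severity and is the readout for
therapies that suppress aberrant splicing or farnesylation, but antibodies
cannot distinguish the proteoforms reliably or quantitatively. A targeted
mass-spectrometry assay can: each proteoform (mature lamin A, farnesylated
prelamin A, progerin) yields a distinguishing tryptic *surrogate peptide*,
including the C-terminal junction peptide of progerin that still carries the
farnesyl (+204.1878 Da) and O-methyl (+14.0157 Da) groups and fragments
through a characteristic farnesyl neutral loss.

`laminprm` is the desk side of such an assay, end to end:

- **Mass calculus** for peptides with noncanonical modifications —
  carbamidomethyl Cys, farnesyl + O-methyl C-termini, and 13C/15N
  heavy labels: precursors, b/y series, neutral losses, label shifts.
- **Proteoform derivation** from a prelamin A sequence via the processing
  rules (farnesylation of the CAAX Cys, AAX cleavage, carboxymethylation,
  Zmpste24 removal of the 15 C-terminal residues), in-silico tryptic
  digestion, and signature-peptide selection.
- **Transition-table design**: MS3 and MS2-XIC trace definitions, heavy
  companion rows for stable-isotope dilution, retention-time scheduling,
  CSV interchange. The three published panels (mouse relative, human
  relative, human absolute) are regenerated from sequence alone.
- **Quantification** from mzML: extracted ion chromatograms matched through
  the full selection path, trapezoidal integration, trace combination,
  relative (internal-control = 100) and absolute quantification,

      amount = (A_light / A_heavy) · spike_fmol · 100 / protein_µg,

  with replicate mean ± sd and CV%, and detection calls
  (`quantified` / `detected_below_loq` / `not_detected`).
- **A synthetic-run generator** producing time-scheduled PRM runs (Gaussian
  elution, multiplicative + additive noise, co-eluting isotopologues) with
  full ground-truth bookkeeping, so the entire pipeline is testable without
  instrument data.

## Worked example

Design the absolute-quantification panel, simulate a triplicate progeria
fibroblast experiment, and quantify it:

```sh
laminprm design --published-panel human_absolute -o panel.csv
laminprm simulate --scenario hgps_fibroblasts --seed 7 --replicates 3 -o sim/
laminprm quantify --panel sim/hgps_fibroblasts_panel.csv -o results.tsv \
    sim/hgps_fibroblasts_rep*.mzML
```

which prints (stderr):

```
truth IC: 176
truth LA: 133
truth hFP: 43
IC: mean=176.2 cv=0.6% status=quantified
LA: mean=133.2 cv=0.3% status=quantified
hFP: mean=42.54 cv=0.7% status=quantified
```

`IC` is the internal-control peptide common to all lamin A proteoforms,
`LA` the mature-lamin-A surrogate and `hFP` the farnesylated progerin
junction peptide; means are fmol per 100 µg loaded protein recovered from
the light/heavy XIC ratios against the spiked standards (the simulated
truths were 176, 133 and 43). `results.tsv` holds the per-run areas,
ratios, amounts and replicate statistics. Simulating `control_fibroblasts`
instead reports `hFP … status=not_detected`, and the `wbc_patient`
scenario reports progerin present but `detected_below_loq`.

The same steps are available as library calls (`build_panel`,
`scenario_fixtures`, `simulate_run`, `quantify_replicates`) — see
`docs/methods.md` for the model details and parameter choices.

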