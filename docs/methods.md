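# Methods

## Model and scope

`laminprm` implements the computational layer of a proteoform-resolved
parallel-reaction-monitoring (PRM) assay for lamin A and farnesylated
progerin. The package makes three modeling commitments:

1. **Proteoforms are derived, not enumerated.** From a prelamin A sequence
   the processing rules produce the four forms: nascent prelamin A;
   farnesylated prelamin A (CAAX Cys farnesylated, last three residues
   removed, new C-terminus O-methylated); mature lamin A (18 C-terminal
   residues removed in total, no lipid); and progerin (a 50-residue
   deletion containing the Zmpste24 site, then farnesylation and AAX
   cleavage but no final cleavage). The farnesyl + O-methyl pair is modeled
   as two stacked modifications on the terminal Cys so each can be toggled
   independently — required for neutral-loss calculus, where the farnesyl
   delta is dropped while the methyl ester survives.
2. **Surrogate uniqueness is judged within the assay's proteoform set**,
   not against a whole proteome; and by default against the *observable*
   forms (mature lamin A, farnesylated prelamin A, progerin). Nascent
   prelamin A is a transient processing intermediate: every internal
   peptide of farnesylated prelamin A also occurs in it, so including it
   would make "unique to farnesylated prelamin A" unsatisfiable for any
   unmodified peptide while changing nothing an instrument can see.
3. **Quantification is ratio-based.** Relative mode normalizes combined
   trace areas to the internal-control peptide (assigned 100). Absolute
   mode uses stable-isotope dilution: amount = (A_light/A_heavy) ·
   spike_fmol · 100/protein_µg. Because standards are spiked after
   digestion, losses upstream of the spike are not corrected; results
   carry that caveat in their notes field.

## Mass calculus

Monoisotopic residue masses come from the standard table in
`pyteomics.mass`; the other constants are m(H+) = 1.00727646677 Da,
water = 18.0105646863 Da, carbamidomethyl +57.021464, O-methyl +14.015650,
farnesyl +204.187801 (C15H24), Δ13C = 1.0033548, Δ15N = 0.9970349.
Internal arithmetic is full double precision; values destined for
transition tables are rounded half-even to 4 decimals. Fragment
conventions: y_n sums the n C-terminal residues plus water, b_n the n
N-terminal residues, each plus z protons over z; modifications and the
heavy label shift a fragment only when their residue lies inside it.
Fragments monitored downstream of a farnesyl neutral loss are computed on
the defarnesylated, still O-methylated species — stated as an explicit
flag on the trace, never an implicit rule.

One deliberate correction: the published table for the heavy human
farnesylated peptide lists a neutral-loss trace value that equals the
light value plus *twice* the single-alanine label shift, while the same
row's precursor and b12 values carry the shift once. The package computes
the self-consistent value (1282.5450 = 1278.5379 + 4.0071), and the
reference values frozen in the test suite document the substitution.
The tolerance used for table comparisons is ±0.0015 Th, which also absorbs
the last-digit rounding jitter visible between duplicate printings of the
heavy-peptide precursor (743.8700 vs 743.8701).

## Digestion and surrogate selection

Trypsin is modeled as cleavage C-terminal to K/R, suppressed before P
(all published surrogates are fully cleaved products or protein C-terminal
peptides, so missed cleavages default to 0). The protein C-terminal
peptide is always emitted, with the proteoform's terminal modifications
attached; peptides are keyed by (sequence, terminal mods), so a
farnesylated peptide never merges with an unmodified twin. Coordinates
are 1-based inclusive throughout, and concatenating a zero-missed-cleavage
digest reconstructs the protein exactly (property-tested).

Selection policy: candidates are 6–25 residues and must end cleanly —
fully tryptic or a modified farnesyl-Cys terminus; ragged products of
post-digest processing boundaries (e.g. the 4–5 residue stub left at the
mature C-terminus) are excluded. One shared-by-all peptide becomes the
internal control (longest wins ties). Each proteoform of interest
contributes its unique peptides; a proteoform with none (mature lamin A,
whose every clean peptide also occurs in farnesylated prelamin A) falls
back to its most discriminating peptide — smallest containing set, longest
first on ties — which reproduces the published choice (the 17-residue
peptide lying inside the progeria deletion). Whether the original
selection applied explicit length/hydrophobicity filters is not recorded
anywhere; these bounds are a documented, conventional choice.

## Bundled sequences

Full-length prelamin A sequences are not printed in any assay table, and
this package is built to run fully offline, so the bundled FASTA files
keyed by UniProt accession (P02545 human, P48678 mouse) are **synthetic
stand-ins**, labelled as such in their filenames and headers. They are
faithful where it matters: published protein lengths (664/665 aa), the
progerin deletion intervals (607–656 / 608–657, both containing the
Zmpste24 site at position length−18), and every published surrogate
peptide and processing junction placed at coordinates consistent with the
processing rules. Regions that never surface in the assay are filler
composed of generic tryptic blocks, constructed so no filler peptide
collides with a panel peptide or outranks one under the selection policy.
Analyses that depend on sequence outside the panel regions (e.g.
proteome-wide uniqueness) are out of scope and would need the real
records.

## Transition design

There is no physical rule that derives *which* fragments an assay
monitors; the published choices are therefore data, recorded per peptide
(`laminprm.panels.TRACE_SCHEMES`), and every m/z is then computed from the
peptide definition — the test suite asserts that each monitored value is
re-derivable through its declared selection path (no orphan numbers).
Traces joined into one combine group are summed into a single quantitative
signal per peptide. An `auto` strategy exists for novel peptides (MS2-XIC
of the neutral-loss ion plus a long defarnesylated b ion for farnesylated
peptides; two long y ions otherwise); it is a reasonable default, not a
claim about optimal fragment intensity. Heavy companion rows re-derive
all traces on the labeled peptide, so precursors always shift by
delta/charge while fragments shift only when they contain the labeled
residue; a monitored fragment without the label is emitted unshifted with
a warning. Retention-time scheduling is optional (the mouse assay is
unscheduled; the human assays use the published windows), and light/heavy
partners always share a window.

## Extraction, integration, detection

XICs match a scan only if stage, path length and every selection level
agree within the m/z tolerance (default ±10 ppm, an Orbitrap-class figure;
configurable in `data/defaults.yaml`). Matching scans without a matching
peak contribute intensity 0; a run with *no* matching scans yields an
empty trace, kept distinct from an all-zero one so absence of acquisition
is never mistaken for absence of analyte. Integration is trapezoidal over
the scheduled window by default; a `peak` method bounded by the local
minima flanking the apex is available. Detection calls: at or below the
noise-floor area (default 200, in integrated intensity·minutes) →
`not_detected`; above it but with light/heavy ratio below the LOQ ratio
(default 0.01, i.e. 1 fmol against a 100-fmol spike) → `detected_below_loq`;
otherwise `quantified`. No numerical definition of the quantification
limit is published for this assay; the ratio threshold is this package's
own operationalization. Replicate statistics are mean, sample sd (n−1)
and CV% = 100·sd/mean; the aggregate status across replicates is the most
optimistic per-replicate call.

## Synthetic runs

The generator emulates a time-scheduled targeted acquisition: scans at a
fixed cycle time (default 1 s) across each row's RT window; each monitored
ion receives response · fmol · Gaussian(rt; apex, σ) · (1 + ε) with
ε ~ N(0, cv) per scan and trace, clipped at zero, plus chemical-noise
peaks uniform in m/z within ±2 Th of the monitored ion with
exponentially distributed intensities (scale 30). Light and heavy
isotopologues co-elute. Defaults: response 2·10⁴ counts/fmol, cv 5%,
5 noise peaks per trace. The generator records, per scan and trace, the
intensity landing within the extraction tolerance of the monitored m/z;
extraction must reproduce this bookkeeping exactly, which makes the
generator the integration oracle.

Scenario fixtures encode the study conditions the assay was developed
under: progeria fibroblasts with ~43 fmol progerin and ~133 fmol lamin A
per 100 µg against 100/100/50 fmol spikes; control fibroblasts with
224 fmol lamin A and zero progerin; patient white blood cells with
progerin above detection but below the LOQ (0.4 fmol vs a 50 fmol spike);
donor cells without it; and mouse scenarios with LA/IC abundance ratios of
≈1 (wild type) and ≈1/3 (progeroid knock-in). Scenario chromatography is
compressed — 4–6 minute windows, σ = 0.08 min, apexes at 2/6/11 min — so a
full design → simulate → quantify cycle finishes in about a second; with
≈19 scans across ±2σ of each peak, per-scan noise averages exactly as it
would on a longer gradient, and nothing downstream depends on the absolute
time scale. The Monte-Carlo precision check runs 100 seeded triplicates of
a compact one-pair assay (72 cycles/run) for the same reason.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: peak tailing and shape anomalies, isotope
envelopes, co-eluting interferences inside the isolation window,
retention-time drift between runs, ion-suppression and response
nonlinearity, and losses during sample preparation. Recovery within 10%
at CV < 20% on these simulations demonstrates the correctness of the
calculus and bookkeeping, not instrument-level accuracy.

## mzML interchange

Runs are written as centroided mzML (64-bit float arrays, zlib, base64;
MS3 expressed as a two-level precursor list) and read back by a
self-contained parser covering the centroided-MSn subset: MS level, scan
start time in minutes or seconds, precursor selection paths, 32/64-bit
arrays, zlib or no compression. Write→read round-trips are exact and
asserted in the suite. Run metadata (sample, loaded protein, spikes)
travels in a JSON sidecar; ground truth goes in a separate sidecar read
only by tests and the CLI log, never by the quantification path.

## Known limitations

- Average-mass calculus, a/c/x/z ions, isotope-envelope prediction and
  collision-energy modeling are out of scope.
- Chromatographic alignment, peak-shape fitting and interference
  refinement are not implemented; integration trusts the scheduled window.
- Absolute amounts are conditional on the post-digestion spike point (see
  above) and on the loaded-protein figure supplied in run metadata.
- The bundled sequences are assay-faithful stand-ins, not database
  records; see “Bundled sequences”.
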