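"""Proteoform derivation, in-silico digestion and signature-peptide selection.

Prelamin A matures through an ordered C-terminal processing pathway:
farnesylation of the CAAX-motif cysteine, endoproteolytic removal of the
last three residues (AAX), carboxyl O-methylation of the new farnesyl-Cys
terminus, and finally Zmpste24 cleavage of the 15 C-terminal residues,
which yields mature lamin A carrying no lipid.  The progeria variant
(progerin) lacks a 50-residue stretch containing the Zmpste24 site, so it
stalls as a permanently farnesylated, O-methylated species.

From a prelamin A sequence this module derives the four proteoforms,
digests them with trypsin, maps every tryptic peptide to the exact subset
of proteoforms that produce it, and selects surrogate peptides: one control
common to all forms plus discriminating peptides per proteoform of
interest.  Peptides carrying the farnesyl + O-methyl terminus never match
unmodified peptides of identical sequence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from .chem import DEFAULT_REGISTRY, Modification, ModifiedPeptide

__all__ = [
    "ProcessingStep",
    "Proteoform",
    "DigestPeptide",
    "SignatureAssignment",
    "SurrogatePolicy",
    "build_proteoforms",
    "tryptic_digest",
    "assign_signatures",
    "select_surrogates",
    "read_fasta",
    "bundled_sequence",
    "BUNDLED_ACCESSIONS",
    "OBSERVABLE_PROTEOFORMS",
]

FARNESYL = DEFAULT_REGISTRY["farnesyl"]
O_METHYL = DEFAULT_REGISTRY["o_methyl"]

#: proteoform names used throughout the package
PRELAMIN = "prelamin_a"
FARN_PRELAMIN = "farnesylated_prelamin_a"
MATURE = "mature_lamin_a"
PROGERIN = "progerin"

#: the species that accumulate in cells and are observable in an assay;
#: nascent (unfarnesylated) prelamin A is a transient intermediate, so
#: surrogate uniqueness is judged against this subset by default.
OBSERVABLE_PROTEOFORMS = (MATURE, FARN_PRELAMIN, PROGERIN)


class ProcessingStep(str, Enum):
    FARNESYLATE_CAAX = "farnesylate_CAAX"
    CLEAVE_AAX = "cleave_AAX"
    CARBOXYMETHYLATE = "carboxymethylate"
    ZMPSTE24_CLEAVE_15 = "zmpste24_cleave_15"


@dataclass(frozen=True)
class Proteoform:
    """A full-length protein product with its processing provenance.

    ``deletion`` is the (start, end) residue interval removed from the
    precursor, 1-based inclusive (the 50-residue progeria deletion).
    Coordinates of digest products always refer to this proteoform's own
    sequence.
    """

    name: str
    sequence: str
    terminal_mods: tuple[Modification, ...] = ()
    provenance: tuple[ProcessingStep, ...] = ()
    deletion: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty proteoform sequence")
        if self.terminal_mods and self.sequence[-1] != "C":
            raise ValueError(
                f"{self.name}: terminal modifications require a C-terminal Cys"
            )


@dataclass(frozen=True)
class DigestPeptide:
    """A proteolytic peptide with 1-based inclusive coordinates in its
    parent sequence and the terminal modifications it inherits (only the
    protein C-terminal peptide can carry them)."""

    sequence: str
    start: int
    end: int
    terminal_mods: tuple[Modification, ...] = ()

    @property
    def key(self) -> tuple[str, tuple[str, ...]]:
        return (self.sequence, tuple(m.name for m in self.terminal_mods))


@dataclass(frozen=True)
class SignatureAssignment:
    """A distinct (sequence, terminal-mod) peptide and the exact subset of
    proteoforms whose digest produces it."""

    peptide: ModifiedPeptide
    found_in: frozenset[str]
    status: str  # unique | shared_all | shared_some

    def __post_init__(self) -> None:
        if self.status == "unique" and len(self.found_in) != 1:
            raise ValueError("unique assignment must map to exactly one proteoform")


def _check_caax(seq: str) -> None:
    if len(seq) < 4 or seq[-4] != "C":
        tail = seq[-4:] if len(seq) >= 4 else seq
        raise ValueError(
            f"sequence does not end in a CAAX motif (C-terminal {tail!r}); "
            "prelamin A processing requires Cys at position length-3"
        )


def build_proteoforms(
    prelamin_seq: str,
    deletion: tuple[int, int] | None = None,
    *,
    strict_deletion: bool = False,
) -> dict[str, Proteoform]:
    """Derive the proteoform set from a prelamin A sequence.

    Returns prelamin A (the input), farnesylated prelamin A (AAX removed,
    farnesyl + O-methyl Cys terminus), mature lamin A (18 C-terminal
    residues removed in total, no terminal mods) and — when ``deletion`` is
    given — progerin (the deletion applied, then farnesylated and AAX
    cleaved but never Zmpste24-processed).

    The Zmpste24 site sits at the mature-lamin boundary (after residue
    ``len - 18``); a deletion interval that does not contain it is
    biologically inconsistent with a stalled proteoform and triggers a
    warning (or an error with ``strict_deletion``).
    """
    _check_caax(prelamin_seq)
    n = len(prelamin_seq)
    farn_steps = (
        ProcessingStep.FARNESYLATE_CAAX,
        ProcessingStep.CLEAVE_AAX,
        ProcessingStep.CARBOXYMETHYLATE,
    )
    out = {
        PRELAMIN: Proteoform(PRELAMIN, prelamin_seq),
        FARN_PRELAMIN: Proteoform(
            FARN_PRELAMIN,
            prelamin_seq[:-3],
            terminal_mods=(FARNESYL, O_METHYL),
            provenance=farn_steps,
        ),
        MATURE: Proteoform(
            MATURE,
            prelamin_seq[:-18],
            provenance=farn_steps + (ProcessingStep.ZMPSTE24_CLEAVE_15,),
        ),
    }
    if deletion is not None:
        start, end = deletion
        if not 1 <= start <= end <= n:
            raise ValueError(f"deletion interval {deletion} outside 1..{n}")
        zmpste24_site = n - 18  # cleavage after this residue
        if not start <= zmpste24_site + 1 <= end + 1:
            msg = (
                f"deletion {start}-{end} does not contain the Zmpste24 "
                f"cleavage site (after residue {zmpste24_site})"
            )
            if strict_deletion:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        deleted = prelamin_seq[: start - 1] + prelamin_seq[end:]
        _check_caax(deleted)
        out[PROGERIN] = Proteoform(
            PROGERIN,
            deleted[:-3],
            terminal_mods=(FARNESYL, O_METHYL),
            provenance=farn_steps,
            deletion=(start, end),
        )
    return out


_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


def tryptic_digest(
    seq: str,
    missed: int = 0,
    *,
    terminal_mods: tuple[Modification, ...] = (),
    min_length: int = 1,
) -> list[DigestPeptide]:
    """Trypsin digestion: cleave C-terminal to K/R except before P.

    The protein C-terminal peptide is always included (with or without a
    K/R terminus) and inherits ``terminal_mods``.  ``missed`` adds products
    with up to that many missed cleavage sites.  Coordinates are 1-based
    inclusive.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    if missed < 0:
        raise ValueError("missed cleavages must be >= 0")
    bounds = [0] + [m.start() for m in _TRYPSIN.finditer(seq)] + [len(seq)]
    # dedupe in case the last residue is a cleavage site
    bounds = sorted(set(bounds))
    out: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed, len(bounds))):
            s, e = bounds[i], bounds[j]
            if e - s < min_length:
                continue
            mods = terminal_mods if e == len(seq) else ()
            out.append(DigestPeptide(seq[s:e], s + 1, e, mods))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def digest_proteoform(pf: Proteoform, missed: int = 0) -> list[DigestPeptide]:
    return tryptic_digest(pf.sequence, missed, terminal_mods=pf.terminal_mods)


def _as_modified_peptide(pep: DigestPeptide) -> ModifiedPeptide:
    mods = tuple((len(pep.sequence), m) for m in pep.terminal_mods)
    return ModifiedPeptide(pep.sequence, mods)


def assign_signatures(
    proteoforms: dict[str, Proteoform] | list[Proteoform],
    digests: dict[str, list[DigestPeptide]] | None = None,
) -> list[SignatureAssignment]:
    """Map every distinct (sequence, terminal-mod) digest peptide to the
    exact subset of proteoforms containing it.

    The result is independent of the order proteoforms are supplied
    (sorted by peptide sequence, then modifications).
    """
    if isinstance(proteoforms, list):
        proteoforms = {p.name: p for p in proteoforms}
    if len(proteoforms) < 2:
        raise ValueError("signature assignment needs at least two proteoforms")
    if digests is None:
        digests = {name: digest_proteoform(pf) for name, pf in proteoforms.items()}
    index: dict[tuple[str, tuple[str, ...]], tuple[DigestPeptide, set[str]]] = {}
    for name in proteoforms:
        for pep in digests[name]:
            entry = index.setdefault(pep.key, (pep, set()))
            entry[1].add(name)
    all_names = frozenset(proteoforms)
    out = []
    for key in sorted(index):
        pep, names = index[key]
        found = frozenset(names)
        if len(found) == 1:
            status = "unique"
        elif found == all_names:
            status = "shared_all"
        else:
            status = "shared_some"
        out.append(SignatureAssignment(_as_modified_peptide(pep), found, status))
    return out


@dataclass(frozen=True)
class SurrogatePolicy:
    """Selection policy for panel peptides.

    ``of_interest`` names the proteoforms to be quantified.  Candidates are
    length-bounded and must end cleanly: either fully tryptic (K/R, the
    protein C-terminus included) or a modified farnesyl-Cys terminus;
    ragged products of post-digest processing boundaries are excluded.
    When a proteoform has no strictly unique peptide the policy falls back
    to its most discriminating one (smallest ``found_in``, longest first on
    ties), never a shared-by-all peptide.
    """

    of_interest: tuple[str, ...]
    min_length: int = 6
    max_length: int = 25
    allow_ragged: bool = False
    allow_fallback: bool = True


def _is_clean_terminus(a: SignatureAssignment) -> bool:
    seq = a.peptide.sequence
    return seq[-1] in "KR" or bool(a.peptide.mods)


def select_surrogates(
    assignments: list[SignatureAssignment],
    policy: SurrogatePolicy,
) -> dict[str, list[SignatureAssignment]]:
    """Select the panel: a ``"control"`` entry (shared-by-all peptide) plus,
    per proteoform of interest, its discriminating peptides.

    A proteoform with no admissible peptide maps to an explicit empty list.
    """
    if not assignments:
        raise ValueError("no signature assignments supplied")

    def admissible(a: SignatureAssignment) -> bool:
        if not policy.min_length <= len(a.peptide.sequence) <= policy.max_length:
            return False
        return policy.allow_ragged or _is_clean_terminus(a)

    pool = [a for a in assignments if admissible(a)]
    controls = sorted(
        (a for a in pool if a.status == "shared_all"),
        key=lambda a: (-len(a.peptide.sequence), a.peptide.sequence),
    )
    out: dict[str, list[SignatureAssignment]] = {
        "control": controls[:1],
    }
    for name in policy.of_interest:
        unique = sorted(
            (a for a in pool if a.status == "unique" and name in a.found_in),
            key=lambda a: (-len(a.peptide.sequence), a.peptide.sequence),
        )
        if unique or not policy.allow_fallback:
            out[name] = unique
            continue
        fallback = sorted(
            (
                a
                for a in pool
                if a.status == "shared_some" and name in a.found_in
            ),
            key=lambda a: (len(a.found_in), -len(a.peptide.sequence), a.peptide.sequence),
        )
        out[name] = fallback[:1]
    return out


# ---------------------------------------------------------------------------
# sequence fixtures

#: bundled prelamin A sequences, keyed by UniProt accession.  These are
#: synthetic stand-ins: published protein length, deletion interval and the
#: surrogate-peptide/junction regions are faithful; regions that never
#: surface in the assay are filler (see the FASTA headers).
BUNDLED_ACCESSIONS = {
    "P02545": ("prelamin_a_human_P02545_synthetic.fasta", (607, 656)),
    "P48678": ("prelamin_a_mouse_P48678_synthetic.fasta", (608, 657)),
}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: sequence}``."""
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def bundled_sequence(accession: str) -> tuple[str, tuple[int, int]]:
    """Return (sequence, progerin deletion interval) for a bundled
    accession."""
    try:
        fname, deletion = BUNDLED_ACCESSIONS[accession]
    except KeyError:
        raise KeyError(
            f"no bundled sequence for {accession!r}; "
            f"available: {sorted(BUNDLED_ACCESSIONS)}"
        ) from None
    with resources.as_file(resources.files("laminprm.data") / fname) as p:
        seq = next(iter(read_fasta(p).values()))
    return seq, deletion
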