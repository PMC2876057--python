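"""Aligned mtDNA sequence handling.

Reads and validates multiple-sequence alignments of control-region
sequences with per-record population/year labels, collapses samples to
haplotype spectra, classifies variable sites (singleton /
parsimony-informative, transition / transversion) and detects adjacent-site
"doublet" substitutions — paired changes at neighbouring positions carried
by the same set of sequences, a known feature of fish D-loop evolution.

Coordinates are 1-based and inclusive throughout, matching the convention
used for reporting variable-site positions in the literature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN-")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: integer encoding used internally: A=0 C=1 G=2 T=3, N/- = -1 (ambiguous)
ENCODING = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}
DECODING = np.array(list("ACGT"))


class AlignmentError(ValueError):
    """Ragged or empty alignment."""


class AlphabetError(ValueError):
    """Symbol outside {A,C,G,T,N,-}."""


class LabelError(KeyError):
    """Record id missing from the label map."""


class ScopeError(ValueError):
    """Empty population scope."""


@dataclass
class Record:
    id: str
    population: str
    year: int
    seq: str


@dataclass
class Alignment:
    """A validated, equal-length nucleotide alignment with sample labels."""

    records: list[Record]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        self.length = lengths.pop()
        if self.length == 0:
            raise AlignmentError("zero-length alignment")
        for r in self.records:
            r.seq = r.seq.upper()
            bad = set(r.seq) - ALPHABET
            if bad:
                raise AlphabetError(f"record {r.id!r}: illegal symbols {sorted(bad)}")
            if not r.population:
                raise LabelError(f"record {r.id!r} has an empty population label")

    # -- container sugar ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population, None)
        return list(seen)

    def subset(self, populations: Iterable[str]) -> "Alignment":
        wanted = set(populations)
        recs = [r for r in self.records if r.population in wanted]
        if not recs:
            raise ScopeError(f"no records in populations {sorted(wanted)}")
        return Alignment(records=[Record(r.id, r.population, r.year, r.seq) for r in recs])

    def matrix(self) -> np.ndarray:
        """(n, L) int8 matrix; ambiguous states (N, -) are -1."""
        out = np.empty((len(self.records), self.length), dtype=np.int8)
        table = np.full(128, -2, dtype=np.int8)
        for sym, code in ENCODING.items():
            table[ord(sym)] = code
        for i, r in enumerate(self.records):
            out[i] = table[np.frombuffer(r.seq.encode(), dtype=np.uint8)]
        return out


@dataclass
class HaplotypeSpectrum:
    """Copies per distinct haplotype within a scope."""

    counts: list[int]
    n: int
    nh: int
    members: dict[str, list[str]]  # haplotype id -> record ids

    def __post_init__(self) -> None:
        assert sum(self.counts) == self.n and len(self.counts) == self.nh
        assert self.n >= self.nh >= 1


@dataclass
class SiteClassification:
    variable_positions: list[int]          # 1-based
    singleton_positions: list[int]
    parsimony_informative_positions: list[int]
    substitution_types: dict[int, str]     # position -> transition|transversion|both

    @property
    def n_variable(self) -> int:
        return len(self.variable_positions)

    @property
    def n_singleton(self) -> int:
        return len(self.singleton_positions)

    @property
    def n_parsimony_informative(self) -> int:
        return len(self.parsimony_informative_positions)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read the sidecar label TSV (``id<TAB>population<TAB>year``)."""
    labels: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "population", "year"]:
            raise LabelError(f"label file {path}: expected header id/population/year")
        for line in fh:
            if not line.strip():
                continue
            rid, pop, year = line.rstrip("\n").split("\t")[:3]
            labels[rid] = (pop, int(year))
    return labels


def read_alignment(path: str | Path,
                   labels: Mapping[str, tuple[str, int]] | str | Path) -> Alignment:
    """Read an aligned FASTA plus a label map into a validated :class:`Alignment`.

    ``labels`` maps record id -> (population, year); a path to a label TSV is
    also accepted.
    """
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in labels:
            raise LabelError(f"record {rec.id!r} missing from label map")
        pop, year = labels[rec.id]
        records.append(Record(rec.id, pop, int(year), str(rec.seq).upper()))
    return Alignment(records=records)


def write_alignment(aln: Alignment, fasta_path: str | Path,
                    labels_path: str | Path | None = None) -> None:
    recs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in aln.records]
    SeqIO.write(recs, str(fasta_path), "fasta")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            fh.write("id\tpopulation\tyear\n")
            for r in aln.records:
                fh.write(f"{r.id}\t{r.population}\t{r.year}\n")


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------

def _compatible(a: str, b: str) -> bool:
    """Identity with N as a wildcard; gaps must match exactly."""
    return all(x == y or (x == "N" and y != "-") or (y == "N" and x != "-")
               for x, y in zip(a, b))


def collapse_haplotypes(aln: Alignment,
                        scope: Iterable[str] | None = None,
                        *,
                        n_as_wildcard: bool = True) -> HaplotypeSpectrum:
    """Group identical sequences into haplotypes.

    By default an ``N`` matches any base, so a sequence with sequencing
    ambiguity does not inflate the haplotype count; pass
    ``n_as_wildcard=False`` for exact string identity.  The grouping is
    canonical (independent of record order): unambiguous sequences define
    classes first, sorted lexicographically, and ambiguous sequences join
    the first compatible class.
    """
    sub = aln if scope is None else aln.subset(scope)
    recs = sub.records

    if not n_as_wildcard:
        groups: dict[str, list[str]] = {}
        for r in recs:
            groups.setdefault(r.seq, []).append(r.id)
        reps = sorted(groups)
    else:
        clean = sorted({r.seq for r in recs if "N" not in r.seq})
        ambig = sorted({r.seq for r in recs if "N" in r.seq})
        reps = list(clean)
        assignment: dict[str, str] = {s: s for s in clean}
        for s in ambig:
            for rep in reps:
                if _compatible(s, rep):
                    assignment[s] = rep
                    break
            else:
                reps.append(s)
                assignment[s] = s
        groups = {}
        for r in recs:
            groups.setdefault(assignment[r.seq], []).append(r.id)
        reps = [rep for rep in reps if rep in groups]

    members = {f"H{i + 1:03d}": sorted(groups[rep]) for i, rep in enumerate(reps)}
    counts = [len(v) for v in members.values()]
    return HaplotypeSpectrum(counts=counts, n=sum(counts), nh=len(counts),
                             members=members)


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def classify_sites(aln: Alignment) -> SiteClassification:
    """Classify alignment columns.

    A site is *variable* if at least two distinct unambiguous bases occur,
    *parsimony-informative* if at least two states each occur at least
    twice, otherwise *singleton*.  The substitution type is judged from the
    purine/pyrimidine classes of every observed state pair.
    """
    if len(aln) < 2:
        raise AlignmentError("site classification needs at least two sequences")
    mat = aln.matrix()
    variable, singleton, informative = [], [], []
    subtypes: dict[int, str] = {}
    for j in range(aln.length):
        col = mat[:, j]
        col = col[col >= 0]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=4)
        states = np.nonzero(counts)[0]
        if states.size < 2:
            continue
        pos = j + 1
        variable.append(pos)
        if np.sum(counts[states] >= 2) >= 2:
            informative.append(pos)
        else:
            singleton.append(pos)
        kinds = set()
        bases = DECODING[states]
        for a in range(len(bases)):
            for b in range(a + 1, len(bases)):
                same_class = ({bases[a], bases[b]} <= PURINES
                              or {bases[a], bases[b]} <= PYRIMIDINES)
                kinds.add("transition" if same_class else "transversion")
        subtypes[pos] = kinds.pop() if len(kinds) == 1 else "both"
    return SiteClassification(variable, singleton, informative, subtypes)


def detect_doublets(aln: Alignment) -> list[tuple[int, int, str]]:
    """Find adjacent variable-site pairs whose minority states co-occur.

    Returns ``(pos, pos+1, pattern)`` with 1-based positions and a pattern
    such as ``"AT->TA"`` (majority pair -> minority pair).  Only clean
    two-state columns are considered, and the set of sequences carrying the
    minority state must be identical at the two sites.
    """
    mat = aln.matrix()
    out: list[tuple[int, int, str]] = []
    for j in range(aln.length - 1):
        pair = []
        for jj in (j, j + 1):
            col = mat[:, jj]
            valid = col >= 0
            counts = np.bincount(col[valid], minlength=4)
            states = np.nonzero(counts)[0]
            if states.size != 2:
                pair = []
                break
            minor = states[np.argmin(counts[states])]
            major = states[np.argmax(counts[states])]
            if counts[minor] == counts[major]:
                pair = []  # no defined minority state
                break
            carriers = frozenset(np.nonzero(valid & (col == minor))[0])
            pair.append((major, minor, carriers))
        if len(pair) == 2 and pair[0][2] == pair[1][2] and pair[0][2]:
            maj = DECODING[pair[0][0]] + DECODING[pair[1][0]]
            mnr = DECODING[pair[0][1]] + DECODING[pair[1][1]]
            out.append((j + 1, j + 2, f"{maj}->{mnr}"))
    return out


def site_report(aln: Alignment) -> "pd.DataFrame":
    """Tabular site report (position, category, substitution type)."""
    import pandas as pd

    cls = classify_sites(aln)
    rows = []
    informative = set(cls.parsimony_informative_positions)
    for pos in cls.variable_positions:
        rows.append({
            "position": pos,
            "category": "parsimony_informative" if pos in informative else "singleton",
            "substitution_type": cls.substitution_types[pos],
        })
    return pd.DataFrame(rows, columns=["position", "category", "substitution_type"])
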