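"""Species-labelled alignment I/O, sequence characteristics and locus concatenation.

The central container is :class:`LabelledAlignment`: an aligned set of
sequences, each carrying a specimen identifier and a binomial species label.
Every downstream stage (distances, gap analysis, identification, trees)
consumes this object.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "LabelError",
    "ConcatenationError",
    "LabelledAlignment",
    "AlignmentStats",
    "default_header_rule",
    "read_alignment",
    "write_alignment",
    "alignment_stats",
    "concatenate",
    "write_partitions",
]

# Encoding used throughout the package: A,C,G,T -> 0..3, anything else
# (gap, N, IUPAC ambiguity) -> MISSING.  Transitions are the even<->even
# and odd<->odd pairs (A<->G, C<->T) under this encoding.
MISSING = np.uint8(255)
_CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

BASES = "ACGT"


class AlignmentError(ValueError):
    """Malformed alignment (unequal lengths, empty input, duplicate ids)."""


class LabelError(ValueError):
    """A sequence header could not be parsed into specimen id + species."""


class ConcatenationError(ValueError):
    """Loci cannot be joined (empty specimen intersection, ambiguous match)."""


def default_header_rule(header: str) -> tuple[str, str]:
    """Parse a FASTA header into ``(specimen_id, species)``.

    The species is taken as the last two underscore- or pipe-separated
    tokens, joined as ``Genus_species``; the specimen id is the full header.
    Raises :class:`LabelError` when fewer than two tokens are present.
    """
    tokens = [t for t in re.split(r"[|_\s]+", header.strip()) if t]
    if len(tokens) < 2:
        raise LabelError(f"cannot parse species from header {header!r}")
    species = f"{tokens[-2]}_{tokens[-1]}"
    return header.strip(), species


@dataclass
class LabelledAlignment:
    """Aligned sequences for one locus (or a concatenation) with labels.

    Parameters
    ----------
    locus_name : str
        Name of the locus, or a ``+``-joined name for concatenations.
    ids, species, sequences : sequences of str
        Parallel per-row records.  Sequences are upper-case over
        ``{A,C,G,T,-,N,IUPAC}`` and all share the same aligned length.
    partitions : list of (locus, start, end)
        1-based inclusive column ranges, recorded by :func:`concatenate`
        so partitioned analyses remain possible.
    """

    locus_name: str
    ids: list[str]
    species: list[str]
    sequences: list[str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise AlignmentError(
                f"{self.locus_name}: an alignment needs at least 2 sequences, "
                f"got {len(self.ids)}"
            )
        if not (len(self.ids) == len(self.species) == len(self.sequences)):
            raise AlignmentError(f"{self.locus_name}: ragged row records")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            offender = next(
                i for i, s in enumerate(self.sequences)
                if len(s) != len(self.sequences[0])
            )
            raise AlignmentError(
                f"{self.locus_name}: unequal sequence lengths "
                f"(record {self.ids[offender]!r} has {len(self.sequences[offender])}, "
                f"first record has {len(self.sequences[0])})"
            )
        if lengths == {0}:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise AlignmentError(f"{self.locus_name}: duplicate specimen id {sid!r}")
            seen.add(sid)
        for sid, sp in zip(self.ids, self.species):
            if not sp:
                raise LabelError(f"{self.locus_name}: empty species label for {sid!r}")
        if not self.partitions:
            self.partitions = [(self.locus_name, 1, self.aligned_length)]

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def aligned_length(self) -> int:
        return len(self.sequences[0])

    @property
    def rows(self) -> list[tuple[str, str, str]]:
        return list(zip(self.ids, self.species, self.sequences))

    def encoded(self) -> np.ndarray:
        """(n_rows, aligned_length) uint8 matrix; non-ACGT states -> 255."""
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_rows, self.aligned_length)
        return _CODE[raw]

    def species_of(self, specimen_id: str) -> str:
        return self.species[self.ids.index(specimen_id)]

    def take(self, indices: Sequence[int], locus_name: str | None = None) -> "LabelledAlignment":
        return LabelledAlignment(
            locus_name or self.locus_name,
            [self.ids[i] for i in indices],
            [self.species[i] for i in indices],
            [self.sequences[i] for i in indices],
            partitions=list(self.partitions),
        )

    def resample_columns(self, columns: Sequence[int], locus_name: str | None = None) -> "LabelledAlignment":
        """Alignment restricted to (possibly repeated) columns, e.g. a bootstrap draw."""
        cols = np.asarray(columns, dtype=int)
        mat = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_rows, self.aligned_length)[:, cols]
        seqs = [row.tobytes().decode("ascii") for row in mat]
        return LabelledAlignment(
            locus_name or self.locus_name, list(self.ids), list(self.species), seqs
        )


@dataclass(frozen=True)
class AlignmentStats:
    """Per-locus sequence characteristics (the left half of a summary table)."""

    locus_name: str
    n_sequences: int
    min_len: int
    max_len: int
    aligned_length: int
    n_variable_sites: int
    pct_variable: float
    n_parsimony_informative: int
    mean_gc: float
    ts_tv_ratio: float | None  # None when no transversion pairs observed


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(
    path: str | Path,
    header_rule: Callable[[str], tuple[str, str]] = default_header_rule,
    locus_name: str | None = None,
) -> LabelledAlignment:
    """Read an aligned multi-FASTA into a :class:`LabelledAlignment`.

    Sequences are upper-cased and U is mapped to T.  Species labels are
    parsed from the headers by ``header_rule`` (default:
    :func:`default_header_rule`).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: empty FASTA file")
    ids, species, seqs = [], [], []
    for rec in records:
        sid, sp = header_rule(rec.description)
        ids.append(sid)
        species.append(sp)
        seqs.append(_normalise(str(rec.seq)))
    return LabelledAlignment(locus_name or path.stem, ids, species, seqs)


def write_alignment(aln: LabelledAlignment, path: str | Path) -> None:
    """Write the alignment as multi-FASTA, headers carrying the specimen id."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def _column_state_counts(enc: np.ndarray) -> np.ndarray:
    """(4, L) counts of unambiguous bases per column."""
    return np.stack([(enc == b).sum(axis=0) for b in range(4)])


def alignment_stats(aln: LabelledAlignment) -> AlignmentStats:
    """Sequence characteristics of one alignment.

    A *variable* site has >=2 distinct unambiguous bases; a
    *parsimony-informative* site has >=2 unambiguous bases each present in
    >=2 sequences.  Gaps, N and ambiguity codes are ignored for state
    counting.  The Ts/Tv ratio is the total number of transition pairs over
    the total number of transversion pairs, summed over all sequence pairs
    and all sites.
    """
    enc = aln.encoded()
    counts = _column_state_counts(enc)  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    n_variable = int((n_states >= 2).sum())
    informative = int(((counts >= 2).sum(axis=0) >= 2).sum())

    # Pairwise transition/transversion totals via per-column state counts:
    # ts pairs = nA*nG + nC*nT ; tv pairs = (nA+nG)*(nC+nT).
    nA, nC, nG, nT = (counts[b].astype(np.int64) for b in range(4))
    ts_pairs = int((nA * nG + nC * nT).sum())
    tv_pairs = int(((nA + nG) * (nC + nT)).sum())
    ts_tv = (ts_pairs / tv_pairs) if tv_pairs > 0 else None

    ungapped = [len(s.replace("-", "")) for s in aln.sequences]
    gc = []
    for row in enc:
        base = row[row != MISSING]
        if base.size:
            gc.append(float(np.isin(base, (1, 2)).mean()))  # C=1, G=2
    return AlignmentStats(
        locus_name=aln.locus_name,
        n_sequences=aln.n_rows,
        min_len=min(ungapped),
        max_len=max(ungapped),
        aligned_length=aln.aligned_length,
        n_variable_sites=n_variable,
        pct_variable=100.0 * n_variable / aln.aligned_length,
        n_parsimony_informative=informative,
        mean_gc=float(np.mean(gc)) if gc else float("nan"),
        ts_tv_ratio=ts_tv,
    )


def concatenate(
    alns: Sequence[LabelledAlignment],
    join_rule: str = "specimen",
    locus_name: str | None = None,
) -> LabelledAlignment:
    """Concatenate loci over shared specimens (or species representatives).

    ``join_rule='specimen'`` keeps specimens present in every input, matched
    by specimen id.  ``join_rule='species'`` keeps one representative per
    species per locus (the first occurrence) for species present in every
    input; the representative of the first locus names the concatenated row.
    Locus boundaries are recorded in ``partitions`` (1-based inclusive).
    """
    if len(alns) < 2:
        raise ConcatenationError("need at least 2 alignments to concatenate")
    name = locus_name or "+".join(a.locus_name for a in alns)

    if join_rule == "specimen":
        keys_per_aln = [list(a.ids) for a in alns]
    elif join_rule == "species":
        keys_per_aln = []
        for a in alns:
            seen: dict[str, str] = {}
            for sid, sp in zip(a.ids, a.species):
                seen.setdefault(sp, sid)
            keys_per_aln.append(list(seen))
    else:
        raise ValueError(f"unknown join_rule {join_rule!r}")

    shared = [k for k in keys_per_aln[0] if all(k in ks for ks in keys_per_aln[1:])]
    if not shared:
        raise ConcatenationError(
            f"{name}: no {join_rule}s shared by all {len(alns)} loci"
        )

    ids, species, seqs = [], [], []
    for key in shared:
        parts = []
        for a in alns:
            if join_rule == "specimen":
                matches = [i for i, sid in enumerate(a.ids) if sid == key]
            else:
                matches = [i for i, sp in enumerate(a.species) if sp == key][:1]
            if len(matches) != 1:
                raise ConcatenationError(
                    f"{name}: {key!r} matches {len(matches)} rows in {a.locus_name}"
                )
            parts.append(matches[0])
        row0 = parts[0]
        ids.append(alns[0].ids[row0])
        species.append(alns[0].species[row0])
        seqs.append("".join(a.sequences[i] for a, i in zip(alns, parts)))

    partitions, offset = [], 0
    for a in alns:
        partitions.append((a.locus_name, offset + 1, offset + a.aligned_length))
        offset += a.aligned_length
    return LabelledAlignment(name, ids, species, seqs, partitions=partitions)


def write_partitions(aln: LabelledAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tstart\tend\n")
        for locus, start, end in aln.partitions:
            fh.write(f"{locus}\t{start}\t{end}\n")
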