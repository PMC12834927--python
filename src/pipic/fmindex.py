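"""FM-indexed protein database with fuzzy, bidirectional tag matching.

The target and shuffled-decoy protein sequences are concatenated with '.'
separators into one long text; an FM-index (Burrows-Wheeler transform,
checkpointed occurrence table, sampled suffix array) over that text and
over its reversal supports backward substring search from either end of a
tag. Fuzzy matching walks successively longer tag suffixes and returns the
longest one found, which tolerates an erroneous residue at the tag's
N-terminal end; running the reversed tag against the reversed-text index
tolerates an error at the C-terminal end.
"""

from __future__ import annotations

import random
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import AA_MASSES, fold_il

SEPARATOR = "."


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    sequence: str  # I/L-folded residue string
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = set(self.sequence) - set(AA_MASSES) | (set(self.sequence) & {"I"})
        if bad:
            raise ValueError(f"invalid residues in {self.accession}: {bad}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein (accession, sequence) pairs; accession = first token.

    Residues outside the 20-letter alphabet (B, Z, X, U, O, *) are dropped.
    """
    proteins: list[tuple[str, str]] = []
    acc, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if acc is not None:
                    proteins.append((acc, "".join(chunks)))
                acc = line[1:].split()[0] if len(line) > 1 else "unnamed"
                chunks = []
            elif line:
                chunks.append("".join(a for a in line.upper() if a in AA_MASSES))
    if acc is not None:
        proteins.append((acc, "".join(chunks)))
    return proteins


def build_long_sequence(proteins: list[tuple[str, str]], seed: int
                        ) -> tuple[str, list[tuple[int, int]], list[ProteinEntry]]:
    """Interleave each target with a seeded residue shuffle of itself.

    Returns the long text ``target . decoy . target . decoy . ...``, a
    position map (start offsets parallel to entries) and the entry list
    with decoys carrying a ``DECOY_`` accession prefix. Shuffling preserves
    the residue multiset, hence every decoy peptide mass distribution.
    """
    if not proteins:
        raise ValueError("empty protein database")
    rng = random.Random(seed)
    text_parts: list[str] = []
    starts: list[tuple[int, int]] = []
    entries: list[ProteinEntry] = []
    pos = 0
    for acc, seq in proteins:
        seq = fold_il("".join(a for a in seq.upper() if a in AA_MASSES))
        if not seq:
            continue
        shuffled = list(seq)
        rng.shuffle(shuffled)
        for accession, s, is_decoy in ((acc, seq, False),
                                       ("DECOY_" + acc, "".join(shuffled), True)):
            entries.append(ProteinEntry(accession, s, is_decoy))
            starts.append((pos, len(s)))
            text_parts.append(s + SEPARATOR)
            pos += len(s) + 1
    return "".join(text_parts), starts, entries


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized)."""
    n = codes.size
    rank = codes.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    tmp = np.empty(n, dtype=np.int64)
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        sa = order
        tmp[sa[0]] = 0
        prev, cur = sa[:-1], sa[1:]
        newer = (rank[cur] != rank[prev]) | (key2[cur] != key2[prev])
        tmp[cur] = np.cumsum(newer)
        rank = tmp.copy()
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa.astype(np.int64)


class FMIndex:
    """FM-index over a text, supporting backward search and locate.

    The text is terminated with a sentinel that sorts before every other
    character. The occurrence table is checkpointed every ``occ_rate``
    positions and the suffix array sampled every ``sa_rate`` entries;
    both are performance choices only.
    """

    def __init__(self, text: str, sa_rate: int = 32, occ_rate: int = 128):
        self.text_len = len(text)
        data = text.encode("ascii") + b"\x00"
        arr = np.frombuffer(data, dtype=np.uint8)
        sa = _suffix_array(arr)
        self._bwt = arr[(sa - 1) % arr.size]
        self.sa_rate = sa_rate
        self._sa_sample_mask = (sa % sa_rate == 0)
        self._sa_samples = {int(r): int(sa[r]) for r in
                            np.nonzero(self._sa_mask_ranks(sa))[0]}
        # character counts: C[c] = number of characters < c in the text
        counts = np.bincount(arr, minlength=256)
        self._C = np.concatenate([[0], np.cumsum(counts)[:-1]])
        # checkpointed occurrence counts
        self.occ_rate = occ_rate
        n_cp = (arr.size // occ_rate) + 1
        present = np.unique(self._bwt)
        self._occ_cp = {}
        for ch in present:
            hits = (self._bwt == ch).astype(np.int64)
            cum = np.concatenate([[0], np.cumsum(hits)])
            self._occ_cp[int(ch)] = cum[:: occ_rate].copy()
        self._full_sa = None  # populated lazily only in tests if needed

    def _sa_mask_ranks(self, sa: np.ndarray) -> np.ndarray:
        return sa % self.sa_rate == 0

    def _occ(self, ch: int, i: int) -> int:
        """Occurrences of ch in bwt[:i]."""
        cp = self._occ_cp.get(ch)
        if cp is None:
            return 0
        block = i // self.occ_rate
        base = int(cp[block])
        start = block * self.occ_rate
        if start == i:
            return base
        return base + int(np.count_nonzero(self._bwt[start:i] == ch))

    def _lf(self, r: int) -> int:
        ch = int(self._bwt[r])
        return int(self._C[ch]) + self._occ(ch, r)

    def backward_search(self, query: str) -> tuple[int, int]:
        """Suffix-array interval [lo, hi) of ``query``; empty if absent."""
        lo, hi = 0, self.text_len + 1
        for ch in map(ord, reversed(query)):
            if not 0 <= ch < 256:
                return 0, 0
            lo = int(self._C[ch]) + self._occ(ch, lo)
            hi = int(self._C[ch]) + self._occ(ch, hi)
            if lo >= hi:
                return 0, 0
        return lo, hi

    def _extend_left(self, lo: int, hi: int, ch: int) -> tuple[int, int]:
        lo2 = int(self._C[ch]) + self._occ(ch, lo)
        hi2 = int(self._C[ch]) + self._occ(ch, hi)
        return lo2, hi2

    def locate(self, lo: int, hi: int) -> list[int]:
        """Text positions for a suffix-array interval, via LF walking."""
        out = []
        for r in range(lo, hi):
            steps, rr = 0, r
            while rr not in self._sa_samples:
                rr = self._lf(rr)
                steps += 1
            out.append((self._sa_samples[rr] + steps) % (self.text_len + 1))
        return sorted(out)

    def match(self, query: str) -> list[int]:
        """All text positions where ``query`` occurs (exact)."""
        lo, hi = self.backward_search(query)
        return self.locate(lo, hi) if lo < hi else []


@dataclass
class FMDatabase:
    """Original and reversed FM-indexes plus the protein position map."""

    text: str
    starts: list[tuple[int, int]]
    entries: list[ProteinEntry]
    o_index: FMIndex
    r_index: FMIndex

    @classmethod
    def build(cls, proteins: list[tuple[str, str]], seed: int = 0) -> "FMDatabase":
        text, starts, entries = build_long_sequence(proteins, seed)
        return cls(text, starts, entries, FMIndex(text), FMIndex(text[::-1]))

    def resolve(self, pos: int) -> tuple[ProteinEntry, int]:
        """Map a text position to (protein entry, offset within protein)."""
        idx = bisect_right([s for s, _l in self.starts], pos) - 1
        start, length = self.starts[idx]
        off = pos - start
        if off >= length:
            raise ValueError(f"position {pos} falls on a separator")
        return self.entries[idx], off


def fuzzy_match(tag: str, index: FMIndex) -> tuple[str, tuple[int, int]]:
    """Longest suffix of ``tag`` present in the text, by backward search.

    Extends the search one character leftward at a time and stops at the
    first failure, returning the last successful suffix and its
    suffix-array interval (empty string and empty interval if even the
    last character is absent).
    """
    if not tag:
        raise ValueError("empty tag")
    lo, hi = 0, index.text_len + 1
    best = ("", (0, 0))
    for i in range(len(tag) - 1, -1, -1):
        lo2, hi2 = index._extend_left(lo, hi, ord(tag[i]))
        if lo2 >= hi2:
            break
        lo, hi = lo2, hi2
        best = (tag[i:], (lo, hi))
    return best


@dataclass(frozen=True)
class Match:
    substring: str
    start_in_tag: int  # index of substring's first residue within the tag
    protein: ProteinEntry
    offset: int        # protein coordinate of the substring's first residue


def bidirectional_match(tag: str, db: FMDatabase,
                        min_match_len: int = 3) -> list[Match]:
    """Locate a tag tolerating one bad stretch at either end.

    Union of the forward fuzzy match (longest suffix, via the original
    index) and the reversed fuzzy match (longest prefix, via the
    reversed-text index), deduplicated on (protein, offset, substring) and
    filtered to matches of at least ``min_match_len`` residues.
    """
    results: dict[tuple[str, int, str], Match] = {}

    suffix, (lo, hi) = fuzzy_match(tag, db.o_index)
    if len(suffix) >= min_match_len:
        for pos in db.o_index.locate(lo, hi):
            entry, off = db.resolve(pos)
            key = (entry.accession, off, suffix)
            results.setdefault(key, Match(suffix, len(tag) - len(suffix),
                                          entry, off))

    rsuffix, (lo, hi) = fuzzy_match(tag[::-1], db.r_index)
    prefix = rsuffix[::-1]  # longest prefix of the tag present in the text
    if len(prefix) >= min_match_len:
        n = db.r_index.text_len
        for rpos in db.r_index.locate(lo, hi):
            pos = n - rpos - len(prefix)
            entry, off = db.resolve(pos)
            key = (entry.accession, off, prefix)
            results.setdefault(key, Match(prefix, 0, entry, off))

    return sorted(results.values(),
                  key=lambda m: (m.protein.accession, m.offset, m.substring))
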