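"""Fragment-based average nucleotide identity (ANI) estimation.

Cross-reactivity flagging between source categories only needs coarse
discrimination around the conventional 95% species boundary, so this
estimator cuts the query genome into non-overlapping fragments, places
each fragment on the reference by shared-k-mer seeding followed by
ungapped extension, and averages the per-fragment identities of the
fragments that place convincingly.  No indel alignment is attempted:
the placement is a single diagonal, which is exact for genomes that
differ only by substitutions and adequate for flagging purposes
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

_COMP = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")

# candidate diagonals evaluated per fragment, most-seeded first
_MAX_CANDIDATE_OFFSETS = 32


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AniResult:
    """Outcome of one query-vs-reference ANI estimation.

    ``ani_percent`` is ``None`` when no fragment placed above the
    identity floor (the genomes are unrelated at this resolution).
    """

    query_id: str
    reference_id: str
    ani_percent: float | None
    aligned_fraction: float
    n_fragments_used: int

    @property
    def defined(self) -> bool:
        return self.ani_percent is not None


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


@dataclass(frozen=True)
class _RefContext:
    """Precomputed per-reference state, shareable across queries."""

    fwd_arr: np.ndarray
    rev_arr: np.ndarray
    fwd_index: dict
    rev_index: dict

    @classmethod
    def build(cls, ref_seq: str, kmer_len: int) -> "_RefContext":
        fwd = ref_seq
        rev = revcomp(ref_seq)
        return cls(
            fwd_arr=np.frombuffer(fwd.encode(), dtype=np.uint8),
            rev_arr=np.frombuffer(rev.encode(), dtype=np.uint8),
            fwd_index=_kmer_index(fwd, kmer_len),
            rev_index=_kmer_index(rev, kmer_len),
        )


def _best_placement(
    fragment: np.ndarray,
    fragment_str: str,
    ref_arr: np.ndarray,
    index: Mapping[str, list[int]],
    k: int,
) -> float | None:
    """Identity (fraction) of the best ungapped placement, or None.

    Candidate diagonals are offsets ``ref_pos - frag_pos`` implied by
    shared k-mers; the most-seeded diagonals are scored first and ties
    resolve to the leftmost reference position for determinism.
    Reference overhangs count as mismatches: identity is always
    matches / fragment length.
    """
    flen = len(fragment)
    votes: dict[int, int] = {}
    for i in range(0, flen - k + 1):
        for rpos in index.get(fragment_str[i : i + k], ()):
            off = rpos - i
            votes[off] = votes.get(off, 0) + 1
    if not votes:
        return None
    # most votes first, then leftmost diagonal
    candidates = sorted(votes, key=lambda off: (-votes[off], off))
    best = None
    rlen = len(ref_arr)
    for off in candidates[:_MAX_CANDIDATE_OFFSETS]:
        lo = max(0, -off)
        hi = min(flen, rlen - off)
        if hi <= lo:
            continue
        matches = int(np.count_nonzero(fragment[lo:hi] == ref_arr[off + lo : off + hi]))
        ident = matches / flen
        if best is None or ident > best:
            best = ident
    return best


def estimate_ani(
    query_seq: str,
    ref_seq: str,
    *,
    fragment_len: int = 1000,
    kmer_len: int = 15,
    min_fragment_identity: float = 80.0,
    query_id: str = "query",
    reference_id: str = "reference",
    _ref_context: _RefContext | None = None,
) -> AniResult:
    """Estimate ANI of ``query_seq`` against ``ref_seq``.

    The query is cut into non-overlapping fragments of ``fragment_len``
    bases (the trailing remainder is dropped; a query shorter than one
    fragment is used whole, with a warning).  Each fragment is placed
    on the reference on both strands; per-fragment identity is
    matches / fragment length and fragments below
    ``min_fragment_identity`` percent are discarded.  The ANI is the
    mean identity of the retained fragments.
    """
    if not query_seq or not ref_seq:
        raise ValueError("both sequences must be non-empty")
    if fragment_len < kmer_len:
        raise ValueError("fragment_len must be at least kmer_len")

    query_seq = query_seq.upper()
    ref_seq = ref_seq.upper()
    if len(query_seq) < fragment_len:
        warnings.warn(
            f"query {query_id!r} shorter than fragment_len; using one truncated fragment",
            stacklevel=2,
        )
        starts = [0]
        frag_end = len(query_seq)
    else:
        starts = list(range(0, len(query_seq) - fragment_len + 1, fragment_len))
        frag_end = fragment_len

    ctx = _ref_context or _RefContext.build(ref_seq, kmer_len)

    identities: list[float] = []
    n_total = len(starts)
    for s in starts:
        frag_str = query_seq[s : s + frag_end]
        frag = np.frombuffer(frag_str.encode(), dtype=np.uint8)
        best_f = _best_placement(frag, frag_str, ctx.fwd_arr, ctx.fwd_index, kmer_len)
        best_r = _best_placement(frag, frag_str, ctx.rev_arr, ctx.rev_index, kmer_len)
        cands = [b for b in (best_f, best_r) if b is not None]
        if not cands:
            continue
        ident = max(cands) * 100.0
        if ident >= min_fragment_identity:
            identities.append(ident)

    n_used = len(identities)
    return AniResult(
        query_id=query_id,
        reference_id=reference_id,
        ani_percent=float(np.mean(identities)) if n_used else None,
        aligned_fraction=n_used / n_total if n_total else 0.0,
        n_fragments_used=n_used,
    )


def all_vs_all(
    sequences: Mapping[str, str],
    *,
    fragment_len: int = 1000,
    kmer_len: int = 15,
    min_fragment_identity: float = 80.0,
) -> list[AniResult]:
    """ANI for every ordered pair of distinct genomes in ``sequences``."""
    ids = list(sequences)
    results = []
    for rid in ids:
        ctx = _RefContext.build(sequences[rid].upper(), kmer_len)
        for qid in ids:
            if qid == rid:
                continue
            results.append(
                estimate_ani(
                    sequences[qid],
                    sequences[rid],
                    fragment_len=fragment_len,
                    kmer_len=kmer_len,
                    min_fragment_identity=min_fragment_identity,
                    query_id=qid,
                    reference_id=rid,
                    _ref_context=ctx,
                )
            )
    results.sort(key=lambda r: (r.query_id, r.reference_id))
    return results


def write_ani_tsv(results: Iterable[AniResult], path) -> None:
    """Write defined ANI results as query<TAB>reference<TAB>ani_percent."""
    with open(path, "w") as fh:
        fh.write("query\treference\tani_percent\n")
        for r in results:
            if r.defined:
                fh.write(f"{r.query_id}\t{r.reference_id}\t{r.ani_percent:.4f}\n")
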