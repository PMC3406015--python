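"""Nucleotide-sequence helpers: ORF scanning, dinucleotide-preserving
shuffles, G+C content and random sequence generation."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode()


def longest_orf_length(seq: str) -> int:
    """Length in nt of the longest open reading frame on the forward strand,
    in any of the three frames.

    An ORF runs from an ATG to the first in-frame stop codon (inclusive); an
    ATG with no downstream in-frame stop extends to the last complete codon.
    Returns 0 when no ATG exists.
    """
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOPS:
                best = max(best, i + 3 - start)
                start = None
            i += 3
        if start is not None:
            # open-ended ORF to the last complete codon in this frame
            last = frame + 3 * ((n - frame) // 3)
            best = max(best, last - start)
    return best


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    The sequence is viewed as an Eulerian walk on the 4-letter multigraph of
    dinucleotide edges; edge orderings are randomized and the last edge into
    the terminal vertex is pinned so a complete walk always exists.
    """
    n = len(seq)
    if n < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for i in range(n - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    last = seq[-1]
    # choose, per non-terminal vertex, a final edge forming a tree toward the
    # terminal vertex (guarantees the shuffled walk is completable)
    vertices = list(edges)
    while True:
        final_edge: dict[str, str] = {}
        for v in vertices:
            if v != last:
                final_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # check connectivity: every non-terminal vertex reaches `last`
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in final_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = final_edge[cur]
            if not ok:
                break
        if ok:
            break
    shuffled_edges: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in final_edge:
            rest.remove(final_edge[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[int(k)] for k in perm]
        if v in final_edge:
            ordered.append(final_edge[v])
        shuffled_edges[v] = ordered
    pos = {v: 0 for v in edges}
    out = [seq[0]]
    cur = seq[0]
    for _ in range(n - 1):
        nxt = shuffled_edges[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def remove_start_codons(seq: str) -> str:
    """Mutate every ATG trinucleotide (any frame) to ACG.

    Replacing the middle base with C cannot create a new ATG, so one pass
    leaves the sequence start-codon-free; its longest ORF, and that of every
    substring, is exactly zero. Used by the scenario generator to sculpt
    noncoding sequence with an unambiguous coding-potential signal.
    """
    out = list(seq)
    for i in range(len(out) - 2):
        if out[i] == "A" and out[i + 1] == "T" and out[i + 2] == "G":
            out[i + 1] = "C"
    return "".join(out)
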