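"""Independent brute-force oracles used to check the implementation.

These are deliberately written from the *definitions* (predicates over
candidate spans, pairwise-gap transitive closure) rather than sharing the
implementation's forward-scan structure.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def orf_oracle(
    seq: str,
    min_len: int,
    start_policy: str,
    strand_policy: str,
    genetic_code: int = 1,
) -> set[tuple[int, int, str, int, bool]]:
    """Enumerate valid maximal ORFs from first principles.

    A span (i, j) in a frame is a valid ORF iff: (j - i) % 3 == 0 and
    j > i; no internal stop codon in codons [i, j-3); either codon j-3 is a
    stop (terminated) or j is the frame's last complete codon end and codon
    j-3 is not a stop (open-ended); and under atg_only the codon at i is
    ATG. Of all valid spans sharing a terminus, only the maximal (smallest
    i) is kept; spans shorter than min_len are dropped.

    Returns {(start, end, strand, frame, has_stop)} with start/end on the
    input (plus-strand) sequence.
    """
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stop_codons = set(table.stop_codons)
    results: set[tuple[int, int, str, int, bool]] = set()
    strands = ["+"] if strand_policy == "plus_only" else ["+", "-"]
    for strand in strands:
        s = seq if strand == "+" else _revcomp(seq)
        L = len(s)
        for frame in range(3):
            codon_positions = list(range(frame, L - 2, 3))
            if not codon_positions:
                continue
            last_end = codon_positions[-1] + 3
            is_stop = {i: s[i : i + 3] in stop_codons for i in codon_positions}
            # candidate termini: every stop codon end, plus the open end
            termini = [(i + 3, True) for i in codon_positions if is_stop[i]]
            if not is_stop[codon_positions[-1]]:
                termini.append((last_end, False))
            for j, has_stop in termini:
                # all candidate starts whose span has no internal stop
                valid_starts = []
                i = j - 3 if has_stop else j
                i -= 3
                while i >= frame and not is_stop[i]:
                    if start_policy == "any_sense" or s[i : i + 3] == "ATG":
                        valid_starts.append(i)
                    i -= 3
                if has_stop and start_policy == "any_sense":
                    # the stop codon alone is a degenerate but valid span
                    valid_starts.append(j - 3)
                if not valid_starts:
                    continue
                i0 = min(valid_starts)  # maximality: smallest valid start
                # belt and braces: re-verify the internal-stop predicate
                assert not any(
                    is_stop[k] for k in range(i0, j - 3, 3)
                ), "oracle inconsistency"
                if j - i0 < min_len:
                    continue
                if strand == "+":
                    results.add((i0, j, "+", frame, has_stop))
                else:
                    results.add((L - j, L - i0, "-", frame, has_stop))
    return results


def merge_oracle(matches, merge_dist: int):
    """Naive O(n^2) union-with-slack: transitive closure of pairwise gap <= d.

    Returns a sorted list of (contig, start, end, strand, n_matches), with
    region strand taken from the longest constituent (ties -> '+').
    """
    n = len(matches)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a in range(n):
        for b in range(a + 1, n):
            ma, mb = matches[a], matches[b]
            if ma.contig_id != mb.contig_id:
                continue
            gap = max(ma.start, mb.start) - min(ma.end, mb.end)
            if gap <= merge_dist:
                union(a, b)
    clusters: dict[int, list] = {}
    for idx in range(n):
        clusters.setdefault(find(idx), []).append(matches[idx])
    out = []
    for members in clusters.values():
        max_len = max(m.length for m in members)
        strands = {m.strand for m in members if m.length == max_len}
        strand = "+" if "+" in strands else "-"
        out.append(
            (
                members[0].contig_id,
                min(m.start for m in members),
                max(m.end for m in members),
                strand,
                len(members),
            )
        )
    return sorted(out)
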