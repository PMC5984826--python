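"""A minimal center-star multiple aligner.

Subgroup MSAs are normally an input (computed by a dedicated MSA program
and read from aligned FASTA/Stockholm); this aligner exists so that the
pipeline is self-contained on synthetic fixtures and small inputs.  It
picks the sequence with the highest total pairwise similarity as the
center, aligns every other sequence to it pairwise (BLOSUM62, affine gaps)
and merges the pairwise alignments on the center's coordinates.
"""

from __future__ import annotations

from .families import align_pair, pair_similarity
from .profiles import Msa

__all__ = ["center_star_align"]


def _pair_layout(gapped_center: str, gapped_seq: str, center_len: int):
    """Split one pairwise alignment into per-center-position pieces."""
    inserts: list[list[str]] = [[] for _ in range(center_len + 1)]
    matched: list[str] = []
    ci = 0
    for a, b in zip(gapped_center, gapped_seq):
        if a == "-":
            inserts[ci].append(b)
        else:
            matched.append(b)
            ci += 1
    return inserts, matched


def center_star_align(ids: list[str], sequences: list[str]) -> Msa:
    """Align sequences by the center-star heuristic; returns an :class:`Msa`."""
    if len(ids) != len(sequences) or not ids:
        raise ValueError("need matching, non-empty id and sequence lists")
    if len(ids) == 1:
        return Msa(list(ids), [sequences[0]])

    totals = [
        sum(pair_similarity(s, t) for j, t in enumerate(sequences) if j != i)
        for i, s in enumerate(sequences)
    ]
    c = max(range(len(sequences)), key=lambda i: (totals[i], -i))
    center = sequences[c]
    L = len(center)

    layouts = []
    for i, seq in enumerate(sequences):
        if i == c:
            layouts.append(([[] for _ in range(L + 1)], list(center)))
            continue
        aln = align_pair(center, seq)
        layouts.append(_pair_layout(str(aln[0]), str(aln[1]), L))

    ins_max = [max(len(lay[0][k]) for lay in layouts) for k in range(L + 1)]
    rows = []
    for inserts, matched in layouts:
        parts = []
        for k in range(L + 1):
            block = "".join(inserts[k]).ljust(ins_max[k], "-")
            parts.append(block)
            if k < L:
                parts.append(matched[k])
        rows.append("".join(parts))
    return Msa(list(ids), rows)
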