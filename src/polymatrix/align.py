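"""Local alignment with affine gaps under a custom scoring matrix.

A Gotoh-style Smith-Waterman: three dynamic-programming layers (match,
gap-in-a, gap-in-b), positive-score floor at zero, and a deterministic
traceback that prefers diagonal over up over left on ties so identical
inputs always produce identical alignments. The DP runs on plain Python
lists: at the sequence lengths this pipeline aligns (transcript
fragments, reference proteins) that is faster than vectorised layouts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .submat import SubstitutionMatrix

_NEG = float("-inf")


@dataclass
class LocalAlignment:
    score: float
    aligned_a: str
    aligned_b: str
    start_a: int  # 0-based half-open region on each input
    end_a: int
    start_b: int
    end_b: int


def smith_waterman(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignment:
    """Optimal local alignment score and one optimal alignment.

    ``gap_open`` is charged for the first gapped position and
    ``gap_extend`` for each subsequent one (a length-1 gap costs
    ``gap_open``). Empty input gives score 0 and an empty alignment.
    Traceback ties resolve diagonal > up (gap in b) > left (gap in a).
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be > 0")
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return LocalAlignment(0.0, "", "", 0, 0, 0, 0)
    idx = {c: i for i, c in enumerate(matrix.alphabet)}
    try:
        ai = [idx[c] for c in a]
        bi = [idx[c] for c in b]
    except KeyError as exc:
        raise ValueError(f"residue not in matrix alphabet: {exc}") from exc
    S = matrix.scores.astype(float).tolist()

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[_NEG] * (m + 1) for _ in range(n + 1)]
    best, bi_best, bj_best = 0.0, 0, 0
    for i in range(1, n + 1):
        Si = S[ai[i - 1]]
        Mi, Mp = M[i], M[i - 1]
        Xi, Xp = Ix[i], Ix[i - 1]
        Yi = Iy[i]  # Iy recurrence is within-row
        for j in range(1, m + 1):
            x = Mp[j] - gap_open
            x2 = Xp[j] - gap_extend
            Xi[j] = x if x >= x2 else x2
            y = Mi[j - 1] - gap_open
            y2 = Yi[j - 1] - gap_extend
            Yi[j] = y if y >= y2 else y2
            diag = Mp[j - 1]
            if Xp[j - 1] > diag:
                diag = Xp[j - 1]
            if Iy[i - 1][j - 1] > diag:
                diag = Iy[i - 1][j - 1]
            v = diag + Si[bi[j - 1]]
            if v < 0.0:
                v = 0.0
            Mi[j] = v
            cell = v
            if Xi[j] > cell:
                cell = Xi[j]
            if Yi[j] > cell:
                cell = Yi[j]
            if cell > best:
                best, bi_best, bj_best = cell, i, j
    if best <= 0.0:
        return LocalAlignment(0.0, "", "", 0, 0, 0, 0)

    # traceback from the best cell; layer preference M (diag) > Ix (up) > Iy
    i, j = bi_best, bj_best
    if M[i][j] >= Ix[i][j] and M[i][j] >= Iy[i][j]:
        layer = "M"
    elif Ix[i][j] >= Iy[i][j]:
        layer = "X"
    else:
        layer = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 and j > 0:
        if layer == "M":
            if M[i][j] == 0.0:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            if M[i - 1][j - 1] >= Ix[i - 1][j - 1] and M[i - 1][j - 1] >= Iy[i - 1][j - 1]:
                layer = "M"
            elif Ix[i - 1][j - 1] >= Iy[i - 1][j - 1]:
                layer = "X"
            else:
                layer = "Y"
            i, j = i - 1, j - 1
            if layer == "M" and M[i][j] == 0.0:
                break
        elif layer == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            layer = "M" if M[i - 1][j] - gap_open >= Ix[i - 1][j] - gap_extend else "X"
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            layer = "M" if M[i][j - 1] - gap_open >= Iy[i][j - 1] - gap_extend else "Y"
            j -= 1
    out_a.reverse()
    out_b.reverse()
    return LocalAlignment(
        score=float(best),
        aligned_a="".join(out_a),
        aligned_b="".join(out_b),
        start_a=i,
        end_a=bi_best,
        start_b=j,
        end_b=bj_best,
    )
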