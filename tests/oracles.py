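"""Independent reference implementations used only as test oracles.

Deliberately naive and self-contained: they share no code with the
package (own IUPAC table, own complement, O(n*m) loops, plain DP), so
agreement with the production paths is meaningful.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def window_matches(window: str, pattern: str) -> bool:
    """Genomic N matches nothing, including pattern N."""
    if len(window) != len(pattern):
        raise ValueError("length mismatch")
    return all(b in IUPAC[p] for b, p in zip(window, pattern))


def brute_force_scan(record_id: str, seq: str, pattern: str, spacer: int):
    """All sites as (record_id, strand, ps_start, ps_end, pam_start, pam_end,
    protospacer, pam) tuples, naive sliding window on both strands."""
    k = len(pattern)
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        L = len(s)
        for i in range(spacer, L - k + 1):
            win = s[i : i + k]
            proto = s[i - spacer : i]
            if "N" in proto or not window_matches(win, pattern):
                continue
            if strand == "+":
                out.append((record_id, "+", i - spacer, i, i, i + k, proto, win))
            else:
                out.append(
                    (record_id, "-", L - i, L - i + spacer, L - i - k, L - i, proto, win)
                )
    return sorted(out)


def brute_force_overlaps(site_iv, exon_ivs, mode):
    """Exon indices hit by one site interval; O(#exons) scan.

    site_iv/exon_ivs are (record_id, start, end) triples.
    """
    rid, s, e = site_iv
    hits = []
    for idx, (xrid, xs, xe) in enumerate(exon_ivs):
        if xrid != rid:
            continue
        if mode == "any_overlap":
            if s < xe and xs < e:
                hits.append(idx)
        else:  # full_containment
            if xs <= s and e <= xe:
                hits.append(idx)
    return hits


def nw_affine_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-5.0, ext=-1.0):
    """Global affine-gap alignment score (Gotoh), end gaps penalized.

    open_ scores the first gap column, ext each additional one.
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion from a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + sub
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext, X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])
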