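"""Independent reference implementations used only to check the package.

Each oracle is written from the underlying mathematics (quaternion
superposition, exhaustive search, graph components, textbook two-pass
statistics, the published H-bond pattern rules) and shares no code with
the implementation paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix


def quaternion_rmsd(mobile: np.ndarray, target: np.ndarray, weights=None) -> float:
    """Optimal proper-rotation RMSD via Horn's quaternion eigen method."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    n = len(mobile)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    W = w.sum()
    p = mobile - (w[:, None] * mobile).sum(0) / W
    q = target - (w[:, None] * target).sum(0) / W
    S = (w[:, None] * p).T @ q
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    ga = float((w[:, None] * p * p).sum())
    gb = float((w[:, None] * q * q).sum())
    return float(np.sqrt(max(ga + gb - 2.0 * lam, 0.0) / W))


def single_linkage_partition(matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Connected components of the <=threshold adjacency graph."""
    adj = (matrix <= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def exhaustive_central(members, matrix) -> int:
    members = list(members)
    best, best_sum = None, np.inf
    for m in members:
        s = sum(matrix[m, o] for o in members if o != m)
        if s < best_sum - 1e-15:
            best, best_sum = m, s
    return best


def two_pass_std(values) -> float:
    """Textbook two-pass sample standard deviation."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    return (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5


# --- secondary-structure oracle -------------------------------------------

HB_Q = 27.888
HB_CUT = -0.5


def ss_oracle(struct) -> str:
    """Direct, loop-by-the-book application of the H-bond pattern rules."""
    from msamd.builder import reconstruct_amide_hydrogens

    reconstruct_amide_hydrogens(struct)
    L = struct.n_residues
    N, H = struct.coords["N"], struct.coords["H"]
    C, O, CA = struct.coords["C"], struct.coords["O"], struct.coords["CA"]

    def has_h(i):
        return i > 0 and struct.sequence[i] != "P" and not np.isnan(H[i]).any()

    def hb(i, j):   # N-H of i donates to C=O of j
        if abs(i - j) < 2 or not has_h(i):
            return False
        e = HB_Q * (1 / np.linalg.norm(O[j] - N[i]) + 1 / np.linalg.norm(C[j] - H[i])
                    - 1 / np.linalg.norm(O[j] - H[i]) - 1 / np.linalg.norm(C[j] - N[i]))
        return e < HB_CUT

    turn = {n: [i < L - n and hb(i + n, i) for i in range(L)] for n in (3, 4, 5)}
    mark = {c: [False] * L for c in "HGIETS"}
    for n, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, L - n):
            if turn[n][i - 1] and turn[n][i]:
                for k in range(i, i + n):
                    mark[code][k] = True
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if para or anti:
                mark["E"][i] = mark["E"][j] = True
    for n in (3, 4, 5):
        for i in range(L - n):
            if turn[n][i]:
                for k in range(i + 1, i + n):
                    mark["T"][k] = True
    for i in range(2, L - 2):
        u = CA[i] - CA[i - 2]
        v = CA[i + 2] - CA[i]
        cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        if np.degrees(np.arccos(cosang)) > 70.0:
            mark["S"][i] = True
    out = []
    for i in range(L):
        c = next((k for k in "HEGITS" if mark[k][i]), "C")
        if i in (0, L - 1) and c in "HEGI":
            c = "T" if mark["T"][i] else ("S" if mark["S"][i] else "C")
        out.append(c)
    return "".join(out)
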