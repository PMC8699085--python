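"""Independent brute-force oracles used by the test suite.

These deliberately take different computational routes from the library
code they check (direct O(N²) summations, explicit truth tables, pair
counting) and must stay free of histobias imports.
"""

import numpy as np


def dc_bruteforce(X, Y) -> float:
    """Squared distance correlation via Székely's direct-summation formula.

    Uses dCov² = S1 + S2 − 2·S3 on the raw distance matrices (no explicit
    double centering), looped element by element.
    """
    X = np.atleast_2d(np.asarray(X, float).T).T
    Y = np.atleast_2d(np.asarray(Y, float).T).T
    n = X.shape[0]
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
            b[i, j] = np.sqrt(((Y[i] - Y[j]) ** 2).sum())

    def dcov2(a, b):
        s1 = (a * b).sum() / (n * n)
        s2 = a.sum() * b.sum() / (n ** 4)
        s3 = (a.sum(axis=1) @ b.sum(axis=1)) / (n ** 3)
        return s1 + s2 - 2.0 * s3

    num = dcov2(a, b)
    vx = dcov2(a, a)
    vy = dcov2(b, b)
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(num / np.sqrt(vx * vy))


def msi_label_truth_table(ihc_loss, msi_pcr, braf, meth):
    """Literal re-encoding of the published MSI-H/MSS decision rule.

    Returns "MSI-H", "MSS" or "needs-BRAF".  Written as a plain reading of
    the clinical text, clause by clause, independent of the library logic.
    """
    # clause 1: MSH2, MSH6 or isolated PMS2 loss -> MSI-H outright
    if "MSH2" in ihc_loss:
        return "MSI-H"
    if "MSH6" in ihc_loss:
        return "MSI-H"
    if "PMS2" in ihc_loss and "MLH1" not in ihc_loss:
        return "MSI-H"
    # clause 2: MLH1 loss or MSI positivity triggers BRAF testing
    if "MLH1" in ihc_loss or msi_pcr:
        if braf is None:
            return "needs-BRAF"
        if braf:
            return "MSS"
        # no BRAF mutation: MSI-H regardless of promoter methylation
        return "MSI-H"
    return "MSS"


def auc_pair_counting(scores, labels) -> float:
    """AUC by explicit all-pairs counting with half-credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson2(x, y) -> float:
    """Squared Pearson correlation straight from the textbook formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx = (x * x).sum()
    syy = (y * y).sum()
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    return float(num * num / den)
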