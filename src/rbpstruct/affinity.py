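"""Structure-augmented RNA k-mer features and a low-rank bilinear ridge
regression linking protein amino-acid k-mer content to RNA binding
preferences.

The RNA feature space extends plain 7-mer occurrence counts with five
context-weighted count blocks: each occurrence of a 7-mer contributes, to
every structural context, the mean probability of that context over the
occurrence's seven positions.  Summed over contexts the weighted blocks
reproduce the plain counts exactly, so the augmentation adds information
only where structural profiles actually vary.

The interaction model predicts intensity y_pq of protein p on probe q as
d_p^T W f_q with a rank-r weight matrix W = A B^T, fitted by alternating
kernel ridge updates (each update is exact given the other factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.metrics import average_precision_score

from .structure import CONTEXTS

_NT_INDEX = {b: i for i, b in enumerate("ACGU")}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class AffinityError(ValueError):
    pass


def _kmer_code(seq: str, t: int, k: int) -> int:
    code = 0
    for i in range(k):
        code = code * 4 + _NT_INDEX[seq[t + i]]
    return code


@dataclass
class RnaFeatureMatrix:
    """Probes x (count + 5 context-weighted) k-mer features, sparse CSR.

    Column layout: block 0 holds the 4^k occurrence counts; blocks 1..5
    hold the context-weighted counts in context order S, H, I, M, E.
    """

    matrix: sparse.csr_matrix
    k: int
    probe_ids: list = field(default_factory=list)

    @property
    def n_kmers(self) -> int:
        return 4 ** self.k

    def block(self, which) -> sparse.csr_matrix:
        """'counts' or a context letter -> the corresponding column block."""
        if which == "counts":
            b = 0
        else:
            b = 1 + CONTEXTS.index(which)
        return self.matrix[:, b * self.n_kmers : (b + 1) * self.n_kmers]

    def counts_only(self) -> sparse.csr_matrix:
        return self.block("counts")


def build_rna_features(probes, profiles, k: int = 7,
                       probe_ids=None) -> RnaFeatureMatrix:
    """Structure-augmented k-mer feature matrix.

    Per occurrence of a k-mer, each context's weight is the mean context
    probability over the k positions; features sum the weights over
    occurrences.  Row identity: for each k-mer, the five context features
    sum to the occurrence count.
    """
    n_kmers = 4 ** k
    rows, cols, vals = [], [], []
    for p, (seq, prof) in enumerate(zip(probes, profiles, strict=True)):
        prof = np.asarray(prof, dtype=float)
        if prof.shape != (len(seq), 5):
            raise AffinityError(f"profile {p} not aligned to probe")
        if len(seq) < k:
            raise AffinityError("probe shorter than k")
        csum = np.vstack([np.zeros(5), np.cumsum(prof, axis=0)])
        for t in range(len(seq) - k + 1):
            code = _kmer_code(seq, t, k)
            rows.append(p)
            cols.append(code)
            vals.append(1.0)
            wmean = (csum[t + k] - csum[t]) / k
            for a in range(5):
                if wmean[a] != 0.0:
                    rows.append(p)
                    cols.append((1 + a) * n_kmers + code)
                    vals.append(wmean[a])
    mat = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(probes), 6 * n_kmers)
    ).tocsr()
    ids = list(probe_ids) if probe_ids is not None else [f"probe{i}" for i in range(len(probes))]
    return RnaFeatureMatrix(mat, k, ids)


def build_protein_features(domain_seqs, k_aa: int = 4) -> tuple[sparse.csr_matrix, list]:
    """Amino-acid k-mer count features over the vocabulary observed in the
    input domains.  Returns (proteins x vocab CSR matrix, vocabulary list)."""
    vocab: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for p, seq in enumerate(domain_seqs):
        seq = seq.upper()
        bad = set(seq) - set(AA_ALPHABET)
        if bad:
            raise AffinityError(f"invalid residues {sorted(bad)} in domain {p}")
        if len(seq) < k_aa:
            raise AffinityError("domain shorter than k_aa")
        counts: dict[int, float] = {}
        for t in range(len(seq) - k_aa + 1):
            km = seq[t : t + k_aa]
            j = vocab.setdefault(km, len(vocab))
            counts[j] = counts.get(j, 0.0) + 1.0
        for j, c in counts.items():
            rows.append(p)
            cols.append(j)
            vals.append(c)
    mat = sparse.coo_matrix((vals, (rows, cols)),
                            shape=(len(domain_seqs), len(vocab))).tocsr()
    return mat, sorted(vocab, key=vocab.get)


def half_split(n_or_items, seed: int = 0):
    """Seeded random 50/50 split; returns two disjoint index arrays covering
    range(n)."""
    n = n_or_items if isinstance(n_or_items, int) else len(n_or_items)
    if n < 2:
        raise AffinityError("need at least 2 probes to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


# ---------------------------------------------------------------------------
# bilinear interaction model
# ---------------------------------------------------------------------------


def _solve_sylvester(K, G, rhs, lam):
    """Solve lam * M + K M G = rhs for M via eigendecompositions of the
    symmetric PSD matrices K (m x m) and G (r x r)."""
    kw, kv = np.linalg.eigh(K)
    gw, gv = np.linalg.eigh(G)
    rhs_t = kv.T @ rhs @ gv
    denom = lam + np.outer(kw, gw)
    return kv @ (rhs_t / denom) @ gv.T


class BilinearInteraction:
    """Low-rank bilinear ridge: y_pq = d_p^T A B^T f_q.

    Parameters
    ----------
    Y : (P x Q) array
        Intensity of protein p on probe q.
    protein_features : (P x dp) array or sparse
    rna_features : (Q x df) array or sparse
    rank : int
        Rank of W = A B^T.
    ridge : float
        L2 penalty on A and B.  Both feature blocks are rescaled to unit
        mean squared row norm internally, so the penalty is comparable
        across feature spaces of different dimensionality or scale (the
        rescaling is undone transparently in the returned factors).
    """

    def __init__(self, Y, protein_features, rna_features, rank: int = 5,
                 ridge: float = 1.0):
        self.Y = np.asarray(Y, dtype=float)
        self.D = sparse.csr_matrix(protein_features)
        self.F = sparse.csr_matrix(rna_features)
        P, Q = self.Y.shape
        if self.D.shape[0] != P or self.F.shape[0] != Q:
            raise AffinityError("feature matrices do not match Y dimensions")
        if P < 5:
            raise AffinityError("need at least 5 proteins")
        if rank > min(self.D.shape[1], self.F.shape[1], P, Q):
            raise AffinityError("rank exceeds feasible dimensions")
        self.rank = rank
        self.ridge = ridge
        KD = np.asarray((self.D @ self.D.T).todense())
        KF = np.asarray((self.F @ self.F.T).todense())
        # scale-invariant regularization: unit mean diagonal per kernel
        self._d_scale = float(np.sqrt(max(KD.diagonal().mean(), 1e-300)))
        self._f_scale = float(np.sqrt(max(KF.diagonal().mean(), 1e-300)))
        self._KD = KD / self._d_scale ** 2
        self._KF = KF / self._f_scale ** 2

    def _objective(self, U, V):
        resid = self.Y - U @ V.T
        return float((resid ** 2).sum())

    def fit(self, n_iter: int = 60, seed: int = 0, tol: float = 1e-9):
        rng = np.random.default_rng(seed)
        P, Q = self.Y.shape
        r, lam = self.rank, self.ridge
        # init B via random M coefficients in probe space
        M = rng.normal(0.0, 1.0 / np.sqrt(Q), size=(Q, r))
        V = self._KF @ M          # = F (F^T M)
        prev = np.inf
        history = []
        for it in range(n_iter):
            # A = D^T N;  lam N + KD N (V^T V) = Y V
            N = _solve_sylvester(self._KD, V.T @ V, self.Y @ V, lam)
            U = self._KD @ N
            # B = F^T M;  lam M + KF M (U^T U) = Y^T U
            M = _solve_sylvester(self._KF, U.T @ U, self.Y.T @ U, lam)
            V = self._KF @ M
            obj = self._objective(U, V)
            history.append(obj)
            if prev - obj < tol * max(1.0, prev):
                break
            prev = obj
        # undo the internal kernel normalization so the factors apply to
        # raw feature matrices
        A = np.asarray(self.D.T @ N) / self._d_scale ** 2
        B = np.asarray(self.F.T @ M) / self._f_scale ** 2
        return BilinearInteractionResults(self, A, B, history)


class BilinearInteractionResults:
    """Fitted factors A (dp x r), B (df x r) and diagnostics."""

    def __init__(self, model_spec: BilinearInteraction, A, B, history):
        self.spec = model_spec
        self.A = A
        self.B = B
        self.history = list(history)

    @property
    def objective(self) -> float:
        return self.history[-1]

    def predict(self, protein_features, rna_features) -> np.ndarray:
        """Predicted intensities, proteins x probes."""
        D = sparse.csr_matrix(protein_features)
        F = sparse.csr_matrix(rna_features)
        return np.asarray((D @ self.A) @ (F @ self.B).T)

    def predict_for_protein(self, protein_feature_vector, rna_features) -> np.ndarray:
        d = np.asarray(protein_feature_vector, dtype=float).reshape(1, -1)
        return self.predict(d, rna_features)[0]

    def summary(self) -> str:
        lines = [
            "Low-rank bilinear interaction model",
            "===================================",
            f"proteins x probes:  {self.spec.Y.shape[0]} x {self.spec.Y.shape[1]}",
            f"rank:               {self.spec.rank}",
            f"ridge lambda:       {self.spec.ridge:g}",
            f"iterations:         {len(self.history)}",
            f"final SSE:          {self.objective:.6g}",
        ]
        return "\n".join(lines)


def fit_interaction(protein_features, rna_features, intensities, rank: int = 5,
                    ridge: float = 1.0, seed: int = 0,
                    n_iter: int = 60) -> BilinearInteractionResults:
    """Functional wrapper around :class:`BilinearInteraction`."""
    model = BilinearInteraction(intensities, protein_features, rna_features,
                                rank=rank, ridge=ridge)
    return model.fit(n_iter=n_iter, seed=seed)


def aupr_top_vs_bottom(predictions, measured, top_pct: float = 1.0,
                       bottom_pct: float = 50.0) -> float:
    """AUPR for ranking the top ``top_pct`` % of probes (by measured value)
    against the bottom ``bottom_pct`` %, using the step-wise
    precision-at-each-recall estimator (no interpolation)."""
    pred = np.asarray(predictions, dtype=float)
    meas = np.asarray(measured, dtype=float)
    n = len(meas)
    n_top = int(np.floor(n * top_pct / 100.0))
    n_bottom = int(np.floor(n * bottom_pct / 100.0))
    if n_top < 1 or n_bottom < 1:
        raise AffinityError("top or bottom class empty; need more probes")
    order = np.argsort(-meas, kind="stable")
    top_idx = order[:n_top]
    bottom_idx = order[-n_bottom:]
    idx = np.concatenate([top_idx, bottom_idx])
    labels = np.concatenate([np.ones(n_top), np.zeros(n_bottom)])
    return float(average_precision_score(labels, pred[idx]))
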