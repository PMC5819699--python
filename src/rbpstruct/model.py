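"""Sequence x structure k-mer binding models.

A binding model scores a k-mer w in structural context a as

    score(w, a) = exp( sum_i Phi[i, w_i] ) * Psi[a]

with position-specific log-scale sequence weights Phi (k x 4) and one
non-negative weight Psi[a] per structural context (S, H, I, M, E), kept
normalized to sum to 5 so that an indifferent model has Psi identically 1.
A whole probe is scored occupancy-style by summing the window scores

    score(s, pi) = sum_t exp( sum_i Phi[i, s_{t+i}] ) * sum_a pbar_a(t) Psi[a]

where pbar_a(t) is the mean probability of context a over the k positions
of window t of the probe's structural profile pi.

The fitter is a regularized least-squares stand-in for full k-mer model
inference: multi-start quasi-Newton minimization of the squared error
between probe scores and measured intensities with an L2 penalty on Phi,
exposed statsmodels-style as ``KmerBindingRegression(...).fit()``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .structure import CONTEXTS, CONTEXT_INDEX

_NT = "ACGU"
_NT_INDEX = {b: i for i, b in enumerate(_NT)}


class ModelError(ValueError):
    pass


@dataclass
class BindingModel:
    """Width-k sequence weights plus five structural-context weights."""

    k: int
    seq_weights: np.ndarray  # k x 4, log scale
    ctx_weights: np.ndarray  # 5 non-negative weights, order S,H,I,M,E
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.seq_weights = np.asarray(self.seq_weights, dtype=float)
        self.ctx_weights = np.asarray(self.ctx_weights, dtype=float)
        if self.k < 1:
            raise ModelError("k must be >= 1")
        if self.seq_weights.shape != (self.k, 4):
            raise ModelError(f"seq_weights must be {self.k} x 4")
        if self.ctx_weights.shape != (5,):
            raise ModelError("ctx_weights must have length 5")
        if np.any(self.ctx_weights < 0):
            raise ModelError("ctx_weights must be non-negative")

    def normalized(self) -> "BindingModel":
        """Gauge-fixed copy: Psi sums to 5, with the scale change absorbed
        into Phi so that all scores are unchanged."""
        s = self.ctx_weights.sum()
        if s <= 0:
            raise ModelError("ctx_weights sum to zero")
        c = s / 5.0
        phi = self.seq_weights + np.log(c) / self.k
        return BindingModel(self.k, phi, self.ctx_weights / c, dict(self.metadata))

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def from_consensus(cls, kmer: str, weight: float = 1.0,
                       context: str | None = None, context_weight: float = 3.0,
                       metadata: dict | None = None) -> "BindingModel":
        """Model preferring one k-mer (log-weight ``weight`` per matching
        position) and optionally one structural context."""
        kmer = kmer.upper().replace("T", "U")
        k = len(kmer)
        phi = np.zeros((k, 4))
        for i, b in enumerate(kmer):
            phi[i, _NT_INDEX[b]] = weight
        psi = np.ones(5)
        if context is not None:
            rest = (5.0 - context_weight) / 4.0
            if context_weight >= 5.0 or rest < 0:
                raise ModelError("context_weight must be < 5")
            psi = np.full(5, rest)
            psi[CONTEXT_INDEX[context]] = context_weight
        return cls(k, phi, psi, metadata or {})


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("T", "U")
    try:
        return np.array([_NT_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ModelError(f"invalid nucleotide {exc.args[0]!r}") from None


def score_kmer_context(model: BindingModel, kmer: str, context: str) -> float:
    """Binding score of a single (k-mer, context) pair."""
    if len(kmer) != model.k:
        raise ModelError(f"kmer length {len(kmer)} != model k {model.k}")
    if context not in CONTEXT_INDEX:
        raise ModelError(f"unknown context {context!r}")
    idx = _encode(kmer)
    return float(np.exp(model.seq_weights[np.arange(model.k), idx].sum())
                 * model.ctx_weights[CONTEXT_INDEX[context]])


def _window_terms(model: BindingModel, seq: str, profile: np.ndarray | None):
    """Per-window (sequence factor, context factor) arrays."""
    k = model.k
    idx = _encode(seq)
    if len(idx) < k:
        raise ModelError(f"probe shorter than k = {k}")
    n_win = len(idx) - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    seq_term = np.exp(model.seq_weights[np.arange(k), windows].sum(axis=1))
    if profile is None:
        ctx_term = np.ones(n_win)
    else:
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (len(idx), 5):
            raise ModelError("profile not aligned to sequence")
        win_mean = (
            np.lib.stride_tricks.sliding_window_view(profile, (k, 5))
            .reshape(n_win, k, 5)
            .mean(axis=1)
        )
        ctx_term = win_mean @ model.ctx_weights
    return seq_term, ctx_term


def score_probe(model: BindingModel, seq: str, profile: np.ndarray,
                agg: str = "sum") -> float:
    """Occupancy-style probe score: aggregate of window scores, each the
    sequence factor times the window-mean context probabilities dotted with
    Psi.  ``agg`` is ``sum`` (default) or ``max``."""
    seq_term, ctx_term = _window_terms(model, seq, profile)
    per_window = seq_term * ctx_term
    if agg == "sum":
        return float(per_window.sum())
    if agg == "max":
        return float(per_window.max())
    raise ModelError(f"unknown aggregation {agg!r}")


def score_probe_sequence_only(model: BindingModel, seq: str,
                              profile: np.ndarray | None = None,
                              agg: str = "sum") -> float:
    """Probe score with structure ignored (Psi forced to all-ones); the
    profile argument is accepted and ignored for interface symmetry."""
    seq_term, _ = _window_terms(model, seq, None)
    return float(seq_term.sum() if agg == "sum" else seq_term.max())


def consensus(model: BindingModel) -> tuple[str, str]:
    """Highest-scoring (k-mer, context) pair.

    The score factorizes over positions, so the consensus k-mer takes the
    best base independently at each position; ties break lexicographically
    (A < C < G < U, then context order S, H, I, M, E), matching a
    brute-force argmax over all 4^k x 5 scores.
    """
    best = []
    for i in range(model.k):
        row = model.seq_weights[i]
        best.append(_NT[int(np.argmax(row))])  # argmax takes first max: lexicographic
    ctx = CONTEXTS[int(np.argmax(model.ctx_weights))]
    return "".join(best), ctx


@dataclass
class PreferenceReport:
    protein_id: str
    consensus_kmer: str
    consensus_context: str
    logratio_paired_unpaired: float
    logratio_loop_external: float


def preference_logratios(model: BindingModel, protein_id: str = "",
                         loop_contexts: str = "HIM") -> PreferenceReport:
    """Structural-preference statistics at the consensus k-mer.

    paired/unpaired: log( score(w, S) / max over unpaired contexts ),
    loop/external:   log( max over loop contexts / score(w, E) ),
    natural log; a negative first ratio means the protein prefers its
    consensus k-mer unpaired.  ``loop_contexts`` selects which unpaired
    classes count as "loop" (default hairpin + internal + multibranch).
    """
    if np.any(model.ctx_weights == 0):
        raise ModelError("zero context weight gives an infinite log-ratio")
    w, a = consensus(model)
    score = {c: score_kmer_context(model, w, c) for c in CONTEXTS}
    unpaired = max(score[c] for c in "HIME")
    loop = max(score[c] for c in loop_contexts)
    return PreferenceReport(
        protein_id=protein_id,
        consensus_kmer=w,
        consensus_context=a,
        logratio_paired_unpaired=float(np.log(score["S"] / unpaired)),
        logratio_loop_external=float(np.log(loop / score["E"])),
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class KmerBindingRegression:
    """Least-squares fit of a sequence x structure k-mer binding model.

    Parameters
    ----------
    intensities : array-like
        Measured (or simulated) probe intensities, one per probe.
    probes : list of str
        Probe RNA sequences.
    profiles : list of (L x 5) arrays
        Structural profiles aligned to the probes.
    k : int
        Model width.
    l2_lambda : float
        Ridge penalty on the sequence weights Phi.
    structure : bool
        If False, Psi is fixed to all-ones (sequence-only model).
    """

    def __init__(self, intensities, probes, profiles, k: int = 5,
                 l2_lambda: float = 1e-3, structure: bool = True,
                 agg: str = "sum"):
        y = np.asarray(intensities, dtype=float)
        if len(probes) < 50:
            raise ModelError("need at least 50 probes to fit")
        if len(probes) != len(y) or len(profiles) != len(y):
            raise ModelError("probes, profiles and intensities must align")
        if not np.all(np.isfinite(y)):
            raise ModelError("intensities must be finite")
        if np.std(y) == 0:
            raise ModelError("constant intensities cannot be fit")
        if agg != "sum":
            raise ModelError("fitting supports agg='sum' only")
        self.y = y
        self.k = k
        self.l2_lambda = l2_lambda
        self.structure = structure
        self.nobs = len(y)

        # pack every window of every probe into flat arrays
        win_idx, win_probe, ctx_mean = [], [], []
        for p, (seq, prof) in enumerate(zip(probes, profiles)):
            idx = _encode(seq)
            if len(idx) < k:
                raise ModelError(f"probe {p} shorter than k")
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (len(idx), 5):
                raise ModelError(f"profile {p} not aligned to probe")
            wv = np.lib.stride_tricks.sliding_window_view(idx, k)
            n_win = wv.shape[0]
            win_idx.append(wv)
            win_probe.append(np.full(n_win, p))
            cm = (
                np.lib.stride_tricks.sliding_window_view(prof, (k, 5))
                .reshape(n_win, k, 5)
                .mean(axis=1)
            )
            ctx_mean.append(cm)
        self._win_idx = np.concatenate(win_idx)          # T x k
        self._win_probe = np.concatenate(win_probe)      # T
        self._ctx_mean = np.concatenate(ctx_mean)        # T x 5
        self._pos = np.arange(k)

    # objective over theta = [Phi.ravel(), psi(5 log-weights if structure)]
    def _unpack(self, theta):
        phi = theta[: self.k * 4].reshape(self.k, 4)
        psi = (np.exp(theta[self.k * 4 :])
               if self.structure and len(theta) > self.k * 4 else np.ones(5))
        return phi, psi

    def _objective(self, theta):
        phi, psi = self._unpack(theta)
        fit_psi = self.structure and len(theta) > self.k * 4
        w = np.exp(phi[self._pos, self._win_idx].sum(axis=1))   # T
        c = self._ctx_mean @ psi                                # T
        scores = np.bincount(self._win_probe, weights=w * c, minlength=self.nobs)
        r = scores - self.y
        obj = float(r @ r) + self.l2_lambda * float((phi * phi).sum())
        # gradient
        r_win = r[self._win_probe]
        g_common = 2.0 * r_win * w
        gphi = np.zeros((self.k, 4))
        wc = g_common * c
        for i in range(self.k):
            np.add.at(gphi[i], self._win_idx[:, i], wc)
        gphi += 2.0 * self.l2_lambda * phi
        if fit_psi:
            gpsi = (self._ctx_mean * g_common[:, None]).sum(axis=0) * psi
            grad = np.concatenate([gphi.ravel(), gpsi])
        else:
            grad = gphi.ravel()
        return obj, grad

    def fit(self, n_starts: int = 3, seed: int = 0, max_iter: int = 300,
            init_scale: float = 0.1) -> "KmerBindingResults":
        rng = np.random.default_rng(seed)
        n_par = self.k * 4 + (5 if self.structure else 0)
        # box constraints keep exp() terms finite during line searches
        bounds = [(-8.0, 8.0)] * (self.k * 4) + (
            [(-6.0, 6.0)] * 5 if self.structure else []
        )
        # sequence-weight starting points: the neutral model plus random
        # restarts (identical across structure on/off runs at equal seed)
        phi_starts = [np.zeros(self.k * 4)] + [
            rng.normal(0.0, init_scale, size=self.k * 4)
            for _ in range(n_starts - 1)
        ]

        def minimize_from(theta0, bnds):
            return optimize.minimize(
                self._objective, theta0, jac=True, method="L-BFGS-B",
                bounds=bnds, options={"maxiter": max_iter},
            )

        best = None
        converged = False
        if self.structure:
            # stage 1: multi-start sequence-only phase; stage 2: joint fit
            # warm-started at the best sequence solution (with neutral
            # context weights), plus random joint restarts.  The joint
            # optimum therefore never trails the sequence-only one.
            seq_best = min((minimize_from(p0, bounds[: self.k * 4])
                            for p0 in phi_starts), key=lambda r: r.fun)
            starts = [np.concatenate([seq_best.x, np.zeros(5)])] + [
                np.concatenate([p0, rng.normal(0.0, init_scale, size=5)])
                for p0 in phi_starts[1:]
            ]
        else:
            starts = phi_starts
        for theta0 in starts:
            res = minimize_from(theta0, bounds)
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        if not converged:
            warnings.warn("k-mer binding fit did not fully converge; "
                          "returning best iterate", RuntimeWarning)
        phi, psi = self._unpack(best.x)
        model = BindingModel(self.k, phi, psi).normalized()
        return KmerBindingResults(self, model, float(best.fun), converged,
                                  int(best.nit))


class KmerBindingResults:
    """Fit results: the estimated model plus diagnostics."""

    def __init__(self, model_spec: KmerBindingRegression, model: BindingModel,
                 objective: float, converged: bool, n_iter: int):
        self.spec = model_spec
        self.model = model
        self.objective = objective
        self.converged = converged
        self.n_iter = n_iter

    def predict(self, probes, profiles, agg: str = "sum") -> np.ndarray:
        return np.array([score_probe(self.model, s, p, agg=agg)
                         for s, p in zip(probes, profiles)])

    def preference_report(self, protein_id: str = "") -> PreferenceReport:
        return preference_logratios(self.model, protein_id)

    def summary(self) -> str:
        w, a = consensus(self.model)
        lines = [
            "Sequence x structure k-mer binding model",
            "========================================",
            f"k:                  {self.model.k}",
            f"n probes:           {self.spec.nobs}",
            f"structure weights:  {'fitted' if self.spec.structure else 'fixed (seq-only)'}",
            f"objective (SSE+L2): {self.objective:.6g}",
            f"converged:          {self.converged} ({self.n_iter} iterations)",
            f"consensus:          {w} in context {a}",
            "Psi (S,H,I,M,E):    "
            + ", ".join(f"{v:.3f}" for v in self.model.ctx_weights),
        ]
        if np.all(self.model.ctx_weights > 0):
            rep = self.preference_report()
            lines += [
                f"log paired/unpaired: {rep.logratio_paired_unpaired:+.3f}",
                f"log loop/external:   {rep.logratio_loop_external:+.3f}",
            ]
        return "\n".join(lines)


def fit_model(probes, profiles, intensities, k: int = 5, l2_lambda: float = 1e-3,
              seed: int = 0, structure: bool = True, n_starts: int = 3,
              max_iter: int = 300) -> BindingModel:
    """Functional wrapper around :class:`KmerBindingRegression`."""
    reg = KmerBindingRegression(intensities, probes, profiles, k=k,
                                l2_lambda=l2_lambda, structure=structure)
    return reg.fit(n_starts=n_starts, seed=seed, max_iter=max_iter).model


def all_kmers(k: int):
    """All 4^k RNA k-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product(_NT, repeat=k)]
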