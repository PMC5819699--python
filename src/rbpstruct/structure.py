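"""Secondary-structure ensembles of short RNAs: pairing probabilities,
five-context structural profiles and unstructuredness.

Every nucleotide of an RNA is assigned a probability distribution over five
structural contexts of the Boltzmann ensemble:

    S  stem (base-paired)
    H  hairpin loop
    I  internal or bulge loop
    M  multibranch loop
    E  external region (unpaired, not enclosed by any pair)

Two interchangeable backends are provided.  The ``basic`` backend is a
self-contained McCaskill-style partition function over a minimal energy model
(one additive energy per base pair, no stacking), exact at any length and
verifiable against exhaustive enumeration.  The ``turner`` backend delegates
to the ViennaRNA library (Turner 2004 energies) and mirrors the behaviour of
``RNAplfold -u 1 -W <window> -L <span>``, which is the standard tool for
local pairing probabilities of long RNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Column order of every L x 5 structural profile.
CONTEXTS = "SHIME"
CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS)}

_ALPHABET = set("ACGU")

#: Base pairs allowed by both backends (canonical Watson-Crick plus wobble).
_DEFAULT_PAIR_ENERGIES = {"GC": -3.0, "AU": -2.0, "GU": -1.0}


class StructureError(ValueError):
    """Invalid sequence or folding configuration."""


@dataclass(frozen=True)
class EnergyModel:
    """Energy model and backend selector for folding.

    The ``basic`` backend assigns each base pair a single negative energy
    (kcal/mol) and each structure the sum of its pair energies; ``RT`` is
    kT at 37 degrees C in kcal/mol.
    """

    backend: str = "basic"
    pair_energies: dict = field(default_factory=lambda: dict(_DEFAULT_PAIR_ENERGIES))
    min_hairpin: int = 3
    RT: float = 0.6163

    def __post_init__(self):
        if self.backend not in ("basic", "turner"):
            raise StructureError(f"unknown backend {self.backend!r}")
        if self.min_hairpin < 3:
            raise StructureError("min_hairpin must be >= 3")
        if any(e > 0 for e in self.pair_energies.values()):
            raise StructureError("pair energies must be <= 0")

    def energy_of(self, a: str, b: str):
        """Energy of pair a.b, or None if the bases cannot pair."""
        e = self.pair_energies.get(a + b)
        if e is None:
            e = self.pair_energies.get(b + a)
        return e


@dataclass(frozen=True)
class FoldParams:
    """Folding-window parameters, mirroring RNAplfold conventions.

    window
        Sequences longer than this are folded in sliding windows and
        per-window probabilities averaged (RNAplfold ``-W``).
    max_span
        Maximum allowed distance j - i of a pair (RNAplfold ``-L``).
    shape_energy_threshold
        Free-energy cutoff (kcal/mol) defining "structured" conformations
        for the unstructuredness probability.
    n_samples
        Boltzmann sample size where a stochastic estimate is needed
        (per-structure energies under the turner backend).
    """

    window: int = 80
    max_span: int = 40
    u: int = 1
    shape_energy_threshold: float = -2.5
    n_samples: int = 1000

    def __post_init__(self):
        if self.max_span > self.window:
            raise StructureError("max_span must be <= window")
        if self.u != 1:
            raise StructureError("only u = 1 is supported")


def _validate(seq: str) -> str:
    if not isinstance(seq, str) or len(seq) == 0:
        raise StructureError("empty sequence")
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - _ALPHABET
    if bad:
        raise StructureError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# basic backend: McCaskill-style recursions over the additive pair model
# ---------------------------------------------------------------------------


class _BasicFold:
    """Inside/outside partition-function matrices for one sequence.

    Z[i][j] is the partition function of the subsequence i..j inclusive
    (1 for empty/short intervals).  All structures are pseudoknot-free
    matchings with hairpin loops of at least ``min_hairpin`` unpaired
    bases and pair span j - i <= max_span.
    """

    def __init__(self, seq: str, em: EnergyModel, max_span: int | None = None):
        self.seq = seq
        self.em = em
        self.n = n = len(seq)
        self.max_span = max_span if max_span is not None else n
        # Boltzmann weight of each admissible pair, 0 where not pairable.
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + em.min_hairpin + 1, min(n, i + self.max_span + 1)):
                e = em.energy_of(seq[i], seq[j])
                if e is not None:
                    w[i, j] = math.exp(-e / em.RT)
        self.w = w
        self._inside()

    def _Z(self, i, j):
        """Inside partition function of [i, j], 1 if the interval is empty."""
        if i > j:
            return 1.0
        return self.Z[i][j]

    def _inside(self):
        n = self.n
        Z = np.ones((n, n))
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                total = Z[i][j - 1] if j - 1 >= i else 1.0
                lo = max(i, j - self.max_span)
                for p in range(lo, j - self.em.min_hairpin):
                    if self.w[p, j] > 0.0:
                        left = Z[i][p - 1] if p - 1 >= i else 1.0
                        inner = Z[p + 1][j - 1] if p + 1 <= j - 1 else 1.0
                        total += self.w[p, j] * left * inner
                Z[i][j] = total
        self.Z = Z
        self.Ztot = Z[0][n - 1] if n > 1 else 1.0

    def _outside(self):
        """Zhat[p,q]: partition function of everything outside pair (p,q)."""
        n = self.n
        pairs = [(p, q) for p in range(n) for q in range(p + 1, n) if self.w[p, q] > 0.0]
        pairs.sort(key=lambda pq: pq[1] - pq[0], reverse=True)
        Zhat = np.zeros((n, n))
        for p, q in pairs:
            total = self._Z(0, p - 1) * self._Z(q + 1, n - 1)
            # enclosed by a larger pair (a, b)
            for a in range(max(0, q - self.max_span), p):
                for b in range(q + 1, min(n, a + self.max_span + 1)):
                    if self.w[a, b] > 0.0:
                        total += (
                            self.w[a, b]
                            * Zhat[a, b]
                            * self._Z(a + 1, p - 1)
                            * self._Z(q + 1, b - 1)
                        )
            Zhat[p, q] = total
        self.Zhat = Zhat
        return Zhat

    def pair_probabilities(self) -> np.ndarray:
        """Matrix P[i,j] = Boltzmann probability of pair (i, j)."""
        if not hasattr(self, "Zhat"):
            self._outside()
        n = self.n
        P = np.zeros((n, n))
        for p in range(n):
            for q in range(p + 1, n):
                if self.w[p, q] > 0.0:
                    P[p, q] = self.w[p, q] * self._Z(p + 1, q - 1) * self.Zhat[p, q] / self.Ztot
        return P

    def p_paired(self) -> np.ndarray:
        P = self.pair_probabilities()
        return P.sum(axis=0) + P.sum(axis=1)

    def _single_helix(self):
        """Z1[a][b]: total weight of structures on [a,b] with exactly one
        top-level helix (everything outside that helix unpaired)."""
        n = self.n
        Z1 = np.zeros((n, n))
        for a in range(n):
            run = 0.0
            for b in range(a, n):
                if b > a:
                    run = Z1[a][b - 1]
                add = 0.0
                for p in range(max(a, b - self.max_span), b - self.em.min_hairpin):
                    if self.w[p, b] > 0.0:
                        add += self.w[p, b] * self._Z(p + 1, b - 1)
                Z1[a][b] = run + add
        self.Z1 = Z1
        return Z1

    def _Z1(self, i, j):
        if i > j:
            return 0.0
        return self.Z1[i][j]

    def context_profile(self) -> np.ndarray:
        """Exact L x 5 context distribution of the ensemble.

        For an unpaired position u enclosed most closely by pair (p, q),
        the loop type is decided by the number of top-level helices in
        the loop of (p, q): 0 = hairpin, 1 = internal/bulge, >=2 =
        multibranch.  Because u is unpaired and uncovered inside (p, q),
        the interval splits into independent left/right segments whose
        helix counts add.
        """
        if not hasattr(self, "Zhat"):
            self._outside()
        if not hasattr(self, "Z1"):
            self._single_helix()
        n = self.n
        prof = np.zeros((n, 5))
        prof[:, CONTEXT_INDEX["S"]] = self.p_paired()
        for u in range(n):
            prof[u, CONTEXT_INDEX["E"]] = self._Z(0, u - 1) * self._Z(u + 1, n - 1) / self.Ztot
        for p in range(n):
            for q in range(p + 1, n):
                if self.w[p, q] == 0.0:
                    continue
                base = self.w[p, q] * self.Zhat[p, q] / self.Ztot
                for u in range(p + 1, q):
                    zl = self._Z(p + 1, u - 1)
                    zr = self._Z(u + 1, q - 1)
                    c0 = 1.0
                    c1 = self._Z1(p + 1, u - 1) + self._Z1(u + 1, q - 1)
                    tot = zl * zr
                    prof[u, CONTEXT_INDEX["H"]] += base * c0
                    prof[u, CONTEXT_INDEX["I"]] += base * c1
                    prof[u, CONTEXT_INDEX["M"]] += base * (tot - c0 - c1)
        return prof

    def energy_histogram(self):
        """Counts of structures by integer energy (units of -1 kcal/mol).

        Returns an array ``N`` where N[k] is the number of structures with
        energy exactly -k kcal/mol.  Valid only when all pair energies are
        integers (the default basic model).
        """
        for e in self.em.pair_energies.values():
            if abs(e - round(e)) > 1e-9:
                raise StructureError("energy histogram requires integer pair energies")
        n = self.n
        units = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(n):
                if self.w[i, j] > 0.0:
                    units[i, j] = int(round(-self.em.energy_of(self.seq[i], self.seq[j])))
        one = np.ones(1)

        # C[i][j]: coefficient vector over energy units for interval [i, j]
        C = [[None] * n for _ in range(n)]

        def get(i, j):
            if i > j:
                return one
            return C[i][j]

        def mul(a, b):
            if len(a) == 1 and a[0] == 1.0:
                return b
            if len(b) == 1 and b[0] == 1.0:
                return a
            return np.convolve(a, b)

        def add(a, b):
            if len(a) < len(b):
                a, b = b, a
            out = a.copy()
            out[: len(b)] += b
            return out

        for span in range(0, n):
            for i in range(0, n - span):
                j = i + span
                if span == 0:
                    C[i][j] = one
                    continue
                total = get(i, j - 1)
                for p in range(max(i, j - self.max_span), j - self.em.min_hairpin):
                    if self.w[p, j] > 0.0:
                        term = mul(get(i, p - 1), get(p + 1, j - 1))
                        shift = np.zeros(units[p, j] + 1)
                        shift[units[p, j]] = 1.0
                        total = add(total, mul(term, shift))
                C[i][j] = total
        return get(0, n - 1)


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

_ENUM_MAX = 22


def _enumerate_structures(seq: str, em: EnergyModel, max_span: int | None = None):
    """Yield every pseudoknot-free structure as a list of (i, j) pairs."""
    n = len(seq)
    span = max_span if max_span is not None else n

    def pairable(i, j):
        return (
            j - i > em.min_hairpin
            and j - i <= span
            and em.energy_of(seq[i], seq[j]) is not None
        )

    def rec(i, j):
        if i >= j:
            yield []
            return
        # i unpaired
        for s in rec(i + 1, j):
            yield s
        for k in range(i + em.min_hairpin + 1, j + 1):
            if pairable(i, k):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield [(i, k)] + left + right

    yield from rec(0, n - 1)


def classify_structure(n: int, pairs) -> np.ndarray:
    """Assign each of n positions a context index (into CONTEXTS) for one
    structure given as a list of (i, j) pairs."""
    partner = np.full(n, -1, dtype=int)
    for i, j in pairs:
        partner[i], partner[j] = j, i
    ctx = np.empty(n, dtype=int)

    def scan(lo, hi, enclosing):
        """Assign contexts for the loop spanning [lo, hi] at the level
        directly below ``enclosing`` (None for the external level)."""
        branches = []
        loop_positions = []
        t = lo
        while t <= hi:
            if partner[t] > t:
                branches.append((t, partner[t]))
                t = partner[t] + 1
            else:
                loop_positions.append(t)
                t += 1
        if enclosing is None:
            code = CONTEXT_INDEX["E"]
        elif len(branches) == 0:
            code = CONTEXT_INDEX["H"]
        elif len(branches) == 1:
            code = CONTEXT_INDEX["I"]
        else:
            code = CONTEXT_INDEX["M"]
        for t in loop_positions:
            ctx[t] = code
        for a, b in branches:
            ctx[a] = ctx[b] = CONTEXT_INDEX["S"]
            scan(a + 1, b - 1, (a, b))

    scan(0, n - 1, None)
    return ctx


def exhaustive_boltzmann(seq: str, em: EnergyModel | None = None,
                         max_span: int | None = None):
    """Exact ensemble statistics by brute-force enumeration (len <= 22).

    Returns ``(p_paired, profile, Z)`` where the vector and the L x 5
    profile are exact Boltzmann averages over every pseudoknot-free
    structure.  Serves as the independent oracle for the recursion-based
    engine.
    """
    em = em or EnergyModel()
    seq = _validate(seq)
    n = len(seq)
    if n > _ENUM_MAX:
        raise StructureError(f"enumeration limited to length {_ENUM_MAX}, got {n}")
    Z = 0.0
    p = np.zeros(n)
    prof = np.zeros((n, 5))
    for pairs in _enumerate_structures(seq, em, max_span):
        e = sum(em.energy_of(seq[i], seq[j]) for i, j in pairs)
        w = math.exp(-e / em.RT)
        Z += w
        ctx = classify_structure(n, pairs)
        for t in range(n):
            prof[t, ctx[t]] += w
        for i, j in pairs:
            p[i] += w
            p[j] += w
    p /= Z
    prof /= Z
    return p, prof, Z


def enumerate_energy_distribution(seq: str, em: EnergyModel | None = None):
    """Brute-force (energy, Boltzmann weight) list; oracle for the
    unstructuredness probability."""
    em = em or EnergyModel()
    seq = _validate(seq)
    if len(seq) > _ENUM_MAX:
        raise StructureError("enumeration limited to short sequences")
    out = []
    for pairs in _enumerate_structures(seq, em):
        e = sum(em.energy_of(seq[i], seq[j]) for i, j in pairs)
        out.append((e, math.exp(-e / em.RT)))
    return out


# ---------------------------------------------------------------------------
# turner backend (ViennaRNA)
# ---------------------------------------------------------------------------


def _require_vienna():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise StructureError(
            "the turner backend requires the ViennaRNA python bindings"
        ) from exc
    return RNA


def _turner_p_paired(seq: str, fp: FoldParams) -> np.ndarray:
    RNA = _require_vienna()
    up = RNA.pfl_fold_up(seq, 1, fp.window, fp.max_span)
    # up is 1-based; up[i][1] = P(position i unpaired)
    return 1.0 - np.array([up[i][1] for i in range(1, len(seq) + 1)])


def _turner_profile(seq: str, fp: FoldParams) -> np.ndarray:
    RNA = _require_vienna()
    md = RNA.md()
    md.window_size = min(fp.window, len(seq))
    md.max_bp_span = fp.max_span
    fc = RNA.fold_compound(seq, md, RNA.OPTION_WINDOW)
    acc = {}

    def cb(v, v_size, i, maxsize, what, data):
        data.setdefault(i, {})[what & ~RNA.PROBS_WINDOW_UP] = v[1]

    fc.probs_window(1, RNA.PROBS_WINDOW_UP | RNA.PROBS_WINDOW_UP_SPLIT, cb, acc)
    n = len(seq)
    prof = np.zeros((n, 5))
    loop_cols = {
        RNA.EXT_LOOP: CONTEXT_INDEX["E"],
        RNA.HP_LOOP: CONTEXT_INDEX["H"],
        RNA.INT_LOOP: CONTEXT_INDEX["I"],
        RNA.MB_LOOP: CONTEXT_INDEX["M"],
    }
    for i in range(1, n + 1):
        for flag, col in loop_cols.items():
            prof[i - 1, col] = max(0.0, acc[i].get(flag, 0.0))
    unpaired = prof.sum(axis=1)
    prof[:, CONTEXT_INDEX["S"]] = np.clip(1.0 - unpaired, 0.0, 1.0)
    prof /= prof.sum(axis=1, keepdims=True)
    return prof


def _turner_sample_energies(seq: str, fp: FoldParams, seed: int) -> list[float]:
    """Boltzmann-sample structures and return their free energies (kcal/mol)."""
    RNA = _require_vienna()
    if fp.n_samples < 100:
        raise StructureError("sampling requires n_samples >= 100")
    md = RNA.md()
    md.uniq_ML = 1
    fc = RNA.fold_compound(seq, md)
    fc.pf()
    RNA.init_rand(int(seed) & 0x7FFFFFFF)
    structures = fc.pbacktrack(fp.n_samples)
    return [fc.eval_structure(s) for s in structures]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _windowed(seq, fp, func, width):
    """Average per-position quantities over sliding windows of fp.window."""
    n = len(seq)
    W = fp.window
    acc = np.zeros((n, width))
    cnt = np.zeros(n)
    for s in range(0, n - W + 1):
        sub = seq[s : s + W]
        acc[s : s + W] += func(sub)
        cnt[s : s + W] += 1
    return acc / cnt[:, None]


def pairing_probabilities(seq: str, em: EnergyModel | None = None,
                          fp: FoldParams | None = None) -> np.ndarray:
    """Per-position probability of being base-paired in the ensemble.

    Sequences no longer than ``fp.window`` are folded globally; longer
    sequences are folded in sliding windows and the per-window paired
    probabilities averaged (the turner backend delegates the windowing to
    ViennaRNA's plfold machinery).
    """
    em = em or EnergyModel()
    fp = fp or FoldParams()
    seq = _validate(seq)
    if em.backend == "turner":
        return _turner_p_paired(seq, fp)
    if len(seq) <= fp.window:
        return _BasicFold(seq, em, fp.max_span).p_paired()
    return _windowed(
        seq, fp, lambda s: _BasicFold(s, em, fp.max_span).p_paired()[:, None], 1
    )[:, 0]


def context_profile(seq: str, em: EnergyModel | None = None,
                    fp: FoldParams | None = None, seed: int = 0) -> np.ndarray:
    """L x 5 matrix of per-position context probabilities (columns S,H,I,M,E).

    Both backends compute the profile exactly: the basic backend by
    inside/outside recursions with a loop-type decomposition, the turner
    backend via ViennaRNA's unpaired-probability split by loop type.
    Rows sum to 1; the S column equals ``pairing_probabilities``.
    """
    em = em or EnergyModel()
    fp = fp or FoldParams()
    seq = _validate(seq)
    if em.backend == "turner":
        return _turner_profile(seq, fp)
    if len(seq) <= fp.window:
        return _BasicFold(seq, em, fp.max_span).context_profile()
    return _windowed(seq, fp, lambda s: _BasicFold(s, em, fp.max_span).context_profile(), 5)


def unstructured_probability(seq: str, em: EnergyModel | None = None,
                             fp: FoldParams | None = None, seed: int = 0) -> float:
    """Probability that the molecule is 'unstructured': one minus the total
    Boltzmann probability of conformations with free energy below the
    shape-energy threshold (default -2.5 kcal/mol).

    Exact for the basic backend (integer-energy histogram over the full
    ensemble); estimated from ``fp.n_samples`` Boltzmann samples under the
    turner backend.
    """
    em = em or EnergyModel()
    fp = fp or FoldParams()
    seq = _validate(seq)
    thr = fp.shape_energy_threshold
    if em.backend == "turner":
        energies = _turner_sample_energies(seq, fp, seed)
        frac_structured = np.mean([e < thr for e in energies])
        return float(1.0 - frac_structured)
    fold = _BasicFold(seq, em, min(fp.max_span, len(seq)))
    hist = fold.energy_histogram()
    k = np.arange(len(hist))
    weights = hist * np.exp(k / em.RT)
    Z = weights.sum()
    structured = weights[(-k) < thr].sum()
    return float(1.0 - structured / Z)


def randomize_profile(length: int, seed: int) -> np.ndarray:
    """Random structural profile used as the negative control.

    Each position draws five non-negative random integers (seeded generator,
    uniform on [0, 32767] like a classic libc ``rand()``) and normalizes them
    to a distribution; all-zero draws are redrawn.
    """
    if length < 1:
        raise StructureError("length must be >= 1")
    rng = np.random.default_rng(seed)
    prof = np.empty((length, 5))
    for t in range(length):
        row = rng.integers(0, 32768, size=5)
        while row.sum() == 0:
            row = rng.integers(0, 32768, size=5)
        prof[t] = row / row.sum()
    return prof


def profiles_for_probes(seqs, em: EnergyModel | None = None,
                        fp: FoldParams | None = None, seed: int = 0):
    """Context profiles for a list of sequences (convenience wrapper)."""
    em = em or EnergyModel()
    fp = fp or FoldParams()
    return [context_profile(s, em, fp, seed=seed + i) for i, s in enumerate(seqs)]
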