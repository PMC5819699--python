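"""K-mer level structural-variability statistics.

For every occurrence of every k-mer across a probe set, the occurrence's
structural signal is the mean base-pairing probability over its k
positions.  Per k-mer, the spread (sample SD) of these occurrence means
measures how much the same k-mer's structural context varies across
probes; the center of the per-k-mer SD distribution is the headline
variability statistic.  Correlating a specific k-mer's occurrence means
with the probes' binding intensities tests whether the structural
variability carries binding signal (negative correlation = the protein
prefers that k-mer unpaired).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class KmerStatsError(ValueError):
    pass


def _p_paired_of(profile_or_vector) -> np.ndarray:
    arr = np.asarray(profile_or_vector, dtype=float)
    if arr.ndim == 2:
        return arr[:, 0]  # S column of an L x 5 profile
    return arr


@dataclass
class KmerOccurrenceStats:
    k: int
    occurrences: dict  # kmer -> np.ndarray of occurrence means

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.occurrences.values())

    def summary_frame(self) -> pd.DataFrame:
        """Per-kmer table: occurrence count, mean and sample SD (NaN when
        a k-mer has fewer than two occurrences)."""
        rows = []
        for kmer in sorted(self.occurrences):
            v = self.occurrences[kmer]
            sd = float(np.std(v, ddof=1)) if len(v) >= 2 else np.nan
            rows.append((kmer, len(v), float(np.mean(v)), sd))
        return pd.DataFrame(rows, columns=["kmer", "n_occ", "mean", "sd"])

    def defined_sds(self) -> np.ndarray:
        frame = self.summary_frame()
        return frame["sd"].dropna().to_numpy()


def kmer_pairing_stats(probes, profiles, k: int = 5) -> KmerOccurrenceStats:
    """Collect per-occurrence mean pairing probabilities for every k-mer.

    ``profiles`` may be per-probe pairing-probability vectors or L x 5
    context profiles (the S column is used).
    """
    occ: dict[str, list] = {}
    for seq, prof in zip(probes, profiles, strict=True):
        p = _p_paired_of(prof)
        if len(p) != len(seq):
            raise KmerStatsError(f"profile length {len(p)} != probe length {len(seq)}")
        if len(seq) < k:
            raise KmerStatsError("probe shorter than k")
        csum = np.concatenate([[0.0], np.cumsum(p)])
        for t in range(len(seq) - k + 1):
            occ.setdefault(seq[t : t + k], []).append((csum[t + k] - csum[t]) / k)
    return KmerOccurrenceStats(k, {km: np.asarray(v) for km, v in occ.items()})


def summarize_sd_distribution(kstats: KmerOccurrenceStats, center: str = "median") -> float:
    """Center (median by default, or mean) of the per-k-mer SD distribution,
    over k-mers with at least two occurrences."""
    sds = kstats.defined_sds()
    if len(sds) == 0:
        raise KmerStatsError("no k-mer has two or more occurrences")
    if center == "median":
        return float(np.median(sds))
    if center == "mean":
        return float(np.mean(sds))
    raise KmerStatsError(f"unknown center {center!r}")


def kmer_intensity_correlation(kmer: str, probes, profiles, intensities,
                               per_probe: str = "all"):
    """Pearson correlation between a k-mer's occurrence-mean pairing
    probabilities and the intensities of the probes they occur in.

    Each occurrence contributes one point by default (``per_probe='all'``);
    ``per_probe='best'`` keeps only the occurrence with the highest mean
    pairing probability per probe.  Returns ``(r, p_value, n)``.
    """
    k = len(kmer)
    xs, ys = [], []
    y = np.asarray(intensities, dtype=float)
    for seq, prof, inten in zip(probes, profiles, y, strict=True):
        p = _p_paired_of(prof)
        if len(p) != len(seq):
            raise KmerStatsError("profile length mismatch")
        means = [p[t : t + k].mean() for t in range(len(seq) - k + 1)
                 if seq[t : t + k] == kmer]
        if not means:
            continue
        if per_probe == "best":
            means = [max(means)]
        elif per_probe != "all":
            raise KmerStatsError(f"unknown per_probe mode {per_probe!r}")
        xs.extend(means)
        ys.extend([inten] * len(means))
    n = len(xs)
    if n < 3:
        raise KmerStatsError(f"only {n} occurrence points; need >= 3")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise KmerStatsError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n
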