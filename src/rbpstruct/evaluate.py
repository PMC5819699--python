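"""In vitro and in vivo binding-prediction evaluation.

In vitro: a model trained on one half of a probe set (Set A) predicts
intensities on the other half (Set B); performance is the Pearson
correlation between predicted and measured intensities after clamping
outlier intensities.  In vivo: bound peaks on transcripts are positives,
same-length windows 300 nt downstream are controls; each 40-nt core is
folded with up to 150 nt of flanking sequence, scored with the model, and
performance is the area under the ROC curve.  Substituting random
structural profiles for the true ones is the negative control that
isolates the contribution of structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .model import BindingModel, score_probe, score_probe_sequence_only
from .structure import EnergyModel, FoldParams, context_profile, randomize_profile

logger = logging.getLogger(__name__)


class EvalError(ValueError):
    pass


def clamp_intensities(values, z: float = 4.0) -> np.ndarray:
    """Clamp outlier intensities to mean +/- z * SD (both tails), with the
    mean and SD taken from the input sample (a single pass).

    At the default z = 4 a second application is almost always a no-op; a
    strictly idempotent variant would have to iterate the bounds, which
    degenerates on extreme one-sided outliers.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise EvalError("intensities must be finite")
    mu, sd = v.mean(), v.std(ddof=0)
    return np.clip(v, mu - z * sd, mu + z * sd)


def predict_probes(model: BindingModel, probes, profiles,
                   sequence_only: bool = False) -> np.ndarray:
    if sequence_only:
        return np.array([score_probe_sequence_only(model, s) for s in probes])
    return np.array([score_probe(model, s, p) for s, p in zip(probes, profiles)])


def eval_in_vitro(model: BindingModel, probes_b, profiles_b, intensities_b,
                  clamp_z: float = 4.0, sequence_only: bool = False) -> float:
    """Pearson correlation of predicted vs clamped measured intensities on
    a held-out probe set."""
    y = clamp_intensities(np.asarray(intensities_b, dtype=float), z=clamp_z)
    pred = predict_probes(model, probes_b, profiles_b, sequence_only=sequence_only)
    if np.std(pred) == 0:
        raise EvalError("model produced constant predictions")
    r, _ = stats.pearsonr(pred, y)
    return float(r)


@dataclass
class InvivoDataset:
    """Labeled 40-nt cores with structural profiles for in vivo evaluation."""

    positives: list = field(default_factory=list)   # (seq, L x 5 profile)
    negatives: list = field(default_factory=list)
    n_skipped_pos: int = 0
    n_skipped_ctrl: int = 0
    core: int = 40


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement_rna())


def _extract_folded_core(transcript: str, c0: int, c1: int, strand: str,
                         flank: int, em, fp, seed) -> tuple[str, np.ndarray]:
    """Fold core [c0, c1) with up to ``flank`` nt on each side (truncated at
    transcript bounds) and return the core sequence + profile rows."""
    e0, e1 = max(0, c0 - flank), min(len(transcript), c1 + flank)
    ext = transcript[e0:e1]
    off = c0 - e0
    core_len = c1 - c0
    if strand == "-":
        ext = _revcomp(ext)
        off = e1 - c1
    prof = context_profile(ext, em, fp, seed=seed)
    core_seq = ext[off : off + core_len]
    return core_seq, prof[off : off + core_len]


def make_invivo_dataset(peaks, transcripts, flank: int = 150, core: int = 40,
                        control_offset: int = 300,
                        em: EnergyModel | None = None,
                        fp: FoldParams | None = None,
                        seed: int = 0) -> InvivoDataset:
    """Build positives (central ``core`` nt of each peak) and controls (the
    ``core``-nt window starting ``control_offset`` nt downstream of the peak
    end, strand-aware) from peak intervals on transcripts.

    Peaks shorter than ``core``, peaks on missing transcripts and controls
    falling outside the transcript or overlapping the peak are skipped and
    counted.
    """
    em = em or EnergyModel()
    fp = fp or FoldParams()
    seqs = {rec.id: rec.seq for rec in transcripts} if not isinstance(transcripts, dict) else transcripts
    ds = InvivoDataset(core=core)
    for i, pk in enumerate(peaks):
        if pk.chrom not in seqs:
            raise EvalError(f"transcript {pk.chrom!r} not found")
        tx = seqs[pk.chrom]
        if pk.end > len(tx):
            raise EvalError(f"peak {pk.chrom}:{pk.start}-{pk.end} outside transcript")
        if pk.end - pk.start < core:
            ds.n_skipped_pos += 1
            logger.info("peak %d shorter than core; skipped", i)
            continue
        mid = (pk.start + pk.end) // 2
        c0 = mid - core // 2
        c1 = c0 + core
        ds.positives.append(
            _extract_folded_core(tx, c0, c1, pk.strand, flank, em, fp, seed + 2 * i)
        )
        # control window 'downstream' in transcript orientation
        if pk.strand == "+":
            g0 = pk.end + control_offset
            g1 = g0 + core
        else:
            g1 = pk.start - control_offset
            g0 = g1 - core
        if g0 < 0 or g1 > len(tx) or (g0 < pk.end and g1 > pk.start):
            ds.n_skipped_ctrl += 1
            logger.info("control for peak %d out of bounds or overlapping; skipped", i)
            continue
        ds.negatives.append(
            _extract_folded_core(tx, g0, g1, pk.strand, flank, em, fp, seed + 2 * i + 1)
        )
    return ds


def auc_rank(pos_scores, neg_scores) -> float:
    """AUC by the rank-sum (Mann-Whitney U) formulation; ties count 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise EvalError("need at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def eval_in_vivo(model: BindingModel, dataset: InvivoDataset,
                 sequence_only: bool = False,
                 randomize_seed: int | None = None) -> float:
    """AUC separating positive from control cores by model score.

    With ``randomize_seed`` set, every core's structural profile is replaced
    by a random one (the structure-randomization control).
    """
    def scores(records, seed_base):
        out = []
        for j, (seq, prof) in enumerate(records):
            if sequence_only:
                out.append(score_probe_sequence_only(model, seq))
            else:
                if randomize_seed is not None:
                    prof = randomize_profile(len(seq), randomize_seed + seed_base + j)
                out.append(score_probe(model, seq, prof))
        return out

    return auc_rank(scores(dataset.positives, 0),
                    scores(dataset.negatives, 10_000_000))


@dataclass
class EvalReport:
    """Paired per-experiment metrics for sequence-only vs sequence+structure
    vs randomized-structure runs, with cross-experiment significance."""

    experiment_ids: list
    seq: np.ndarray
    seqstruct: np.ndarray
    randomized: np.ndarray | None = None
    metric: str = "pearson_r"

    def __post_init__(self):
        self.seq = np.asarray(self.seq, dtype=float)
        self.seqstruct = np.asarray(self.seqstruct, dtype=float)
        if self.randomized is not None:
            self.randomized = np.asarray(self.randomized, dtype=float)
        n = len(self.experiment_ids)
        if len(self.seq) != n or len(self.seqstruct) != n:
            raise EvalError("metric vectors must align with experiment ids")

    def improvement_pvalue(self, alternative: str = "two-sided") -> float:
        return paired_improvement_test(self.seq, self.seqstruct,
                                       alternative=alternative)

    def randomized_pvalue(self, alternative: str = "greater") -> float:
        if self.randomized is None:
            raise EvalError("no randomized-structure metrics recorded")
        return paired_improvement_test(self.seq, self.randomized,
                                       alternative=alternative)

    def summary_frame(self):
        import pandas as pd

        data = {"experiment": self.experiment_ids,
                f"{self.metric}_seq": self.seq,
                f"{self.metric}_seqstruct": self.seqstruct}
        if self.randomized is not None:
            data[f"{self.metric}_randomized"] = self.randomized
        return pd.DataFrame(data)


def paired_improvement_test(metrics_a, metrics_b, method: str = "signed_rank",
                            alternative: str = "two-sided") -> float:
    """P-value for paired per-experiment metric differences (B vs A).

    ``signed_rank`` (default) is the Wilcoxon signed-rank test on the paired
    differences; ``rank_sum`` compares the two metric samples as independent
    groups.  ``alternative='greater'`` asks specifically whether B improves
    on A — the form under which a no-effect control yields p near 1.  With
    fewer than 6 pairs the signed-rank branch falls back to its exact
    distribution (with a warning).
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if method == "rank_sum":
        return float(stats.ranksums(b, a, alternative=alternative).pvalue)
    if method != "signed_rank":
        raise EvalError(f"unknown method {method!r}")
    if len(a) != len(b):
        raise EvalError("paired test needs equal-length metric vectors")
    d = b - a
    if np.all(d == 0):
        return 1.0
    mode = "auto"
    if len(d) < 6:
        import warnings

        warnings.warn("fewer than 6 pairs; using exact signed-rank distribution")
        mode = "exact"
    return float(stats.wilcoxon(d, mode=mode, alternative=alternative).pvalue)
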