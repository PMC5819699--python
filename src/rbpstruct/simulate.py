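"""Synthetic data with the statistical structure the analyses assume.

The generators emulate the three experimental data types the pipeline
consumes, so that every stage can be exercised and validated without any
external download:

* short RNA probes (30-41 nt, i.i.d. uniform nucleotides, unique) in the
  style of an RNAcompete probe library;
* probe binding intensities from a planted sequence x structure k-mer
  model plus Gaussian noise;
* pseudo-CLIP transcripts with the planted model's consensus k-mer
  embedded in a controlled structural context (inside a designed hairpin
  loop, inside a stem, or in plain background), with BED peak intervals;
* a panel of synthetic proteins whose intensities follow a planted
  low-rank bilinear interaction between amino-acid k-mer content and
  (RNA 7-mer, context) features.

Every generator is a pure function of its seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .affinity import AA_ALPHABET, build_protein_features, build_rna_features
from .io import IntensityTable, PeakInterval, SequenceRecord
from .model import BindingModel, consensus, score_probe
from .structure import EnergyModel, FoldParams, profiles_for_probes

_NT = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Bundle of generator settings (defaults match the probe design and
    noise regime the analyses assume)."""

    n_probes: int = 2000
    length_range: tuple = (30, 41)
    planted_model: BindingModel | None = None
    noise_sd: float = 0.0
    n_transcripts: int = 50
    transcript_length: int = 600
    sites_per_transcript: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")


def random_probes(n: int, length_range=(30, 41), seed: int = 0,
                  unique: bool = True) -> list[SequenceRecord]:
    """Unique random RNA probes with i.i.d. uniform nucleotides and lengths
    uniform over ``length_range`` (inclusive)."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    lo, hi = length_range
    if unique and 4 ** lo < 100 * n:
        raise SimulationError("uniqueness unattainable at this length/n")
    rng = np.random.default_rng(seed)
    seen = set()
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n:
            raise SimulationError("uniqueness unattainable (rejection limit)")
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(_NT[rng.integers(0, 4, L)])
        if unique:
            if seq in seen:
                continue
            seen.add(seq)
        out.append(SequenceRecord(f"probe{len(out)}", seq))
    return out


def default_planted_model(kmer: str = "UGCAU", seq_weight: float = 1.5,
                          context: str | None = "E",
                          context_weight: float = 3.0) -> BindingModel:
    """Planted binding model used throughout the synthetic benchmarks: a
    single consensus k-mer with moderate per-position log-weight and one
    preferred structural context."""
    return BindingModel.from_consensus(kmer, seq_weight, context, context_weight,
                                       metadata={"planted": True})


def simulate_intensities(probes, profiles, planted_model: BindingModel,
                         noise_sd: float = 0.0, seed: int = 0) -> IntensityTable:
    """Probe intensities y_i = score(planted, s_i, pi_i) + N(0, noise_sd^2)."""
    rng = np.random.default_rng(seed)
    seqs = [p.seq if isinstance(p, SequenceRecord) else p for p in probes]
    ids = [p.id if isinstance(p, SequenceRecord) else f"probe{i}"
           for i, p in enumerate(probes)]
    scores = np.array([score_probe(planted_model, s, pr)
                       for s, pr in zip(seqs, profiles, strict=True)])
    y = scores + rng.normal(0.0, noise_sd, size=len(scores))
    return IntensityTable(ids, y)


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _designed_element(kmer: str, context_target: str, rng) -> tuple[str, int]:
    """Sequence element embedding ``kmer`` in the requested structural
    context; returns (element, offset of kmer within element)."""
    if context_target == "unpaired_loop":
        # GC-only stem of 7 pairs closing a loop that is exactly the k-mer
        arm = "".join(rng.choice(list("GC"), size=7))
        return arm + kmer + _revcomp(arm), 7
    if context_target == "paired_stem":
        # k-mer inside one arm of a clamped stem, 4-nt hairpin loop
        clamp = "".join(rng.choice(list("GC"), size=3))
        arm5 = clamp + kmer
        return arm5 + "GAAA" + _revcomp(arm5), 3
    if context_target == "any":
        return kmer, 0
    raise SimulationError(f"unknown context_target {context_target!r}")


def simulate_transcripts_with_sites(planted_model: BindingModel,
                                    n_transcripts: int = 50,
                                    length: int = 600,
                                    sites_per_transcript: int = 1,
                                    context_target: str = "unpaired_loop",
                                    seed: int = 0,
                                    peak_width: int = 40):
    """Uniform-background transcripts with the planted consensus k-mer
    embedded at recorded positions in a controlled structural context.

    Returns ``(transcripts, peaks)``: SequenceRecord list and BED-style
    PeakInterval list (one ``peak_width``-nt peak centered on each site).
    Transcripts leave >= 400 nt downstream of every site so the standard
    +300 nt control window fits.
    """
    if length < 400:
        raise SimulationError("transcript length must be >= 400")
    kmer, _ = consensus(planted_model)
    if len(kmer) > peak_width:
        raise SimulationError("k-mer longer than peak width")
    rng = np.random.default_rng(seed)
    usable = length - 400 - 60
    if usable < 60 * sites_per_transcript:
        raise SimulationError("transcript too short for requested sites")
    transcripts, peaks = [], []
    for t in range(n_transcripts):
        seq = list("".join(_NT[rng.integers(0, 4, length)]))
        starts = 60 + np.sort(rng.choice(usable // 60, size=sites_per_transcript,
                                         replace=False)) * 60
        name = f"tx{t}"
        for s in starts:
            elem, off = _designed_element(kmer, context_target, rng)
            seq[s : s + len(elem)] = list(elem)
            center = s + off + len(kmer) // 2
            p0 = center - peak_width // 2
            peaks.append(PeakInterval(name, int(p0), int(p0 + peak_width), "+", 1.0))
        transcripts.append(SequenceRecord(name, "".join(seq)))
    return transcripts, peaks


@dataclass
class ProteinPanel:
    """Synthetic protein panel: domains, probes with profiles, and the
    intensity matrix Y (proteins x probes) from a planted bilinear model."""

    domains: list
    probes: list
    profiles: list
    Y: np.ndarray
    rna_features: object
    protein_features: object
    aa_vocab: list = field(default_factory=list)
    planted_signal: np.ndarray | None = None


def simulate_protein_panel(n_proteins: int = 20, k_aa: int = 4,
                           rank: int = 2, seed: int = 0,
                           n_probes: int = 250, rna_k: int = 4,
                           domain_length: int = 60,
                           noise_sd_frac: float = 0.2,
                           structure_loading: bool = True,
                           em: EnergyModel | None = None,
                           fp: FoldParams | None = None) -> ProteinPanel:
    """Panel of synthetic proteins with planted low-rank interaction.

    Each planted component ties a random set of amino-acid k-mers to a
    random set of RNA ``rna_k``-mers.  The default RNA k-mer width is 4
    rather than the feature builder's 7: at a few hundred probes, distinct
    random probes share almost no 7-mers, so the exact-k-mer feature kernel
    degenerates to the identity and no regression method could transfer to
    held-out probes; 4-mers keep every feature observed in many probes at
    this panel size.  With ``structure_loading`` the RNA
    side loads on a context contrast (external minus stem) of those
    k-mers — signal only recoverable with structure-augmented features —
    in addition to their plain counts; without it, on counts alone.
    Noise SD is ``noise_sd_frac`` times the SD of the planted signal.
    """
    if n_proteins < 5:
        raise SimulationError("need at least 5 proteins")
    em = em or EnergyModel(backend="turner")
    fp = fp or FoldParams()
    rng = np.random.default_rng(seed)

    domains = [SequenceRecord(f"prot{p}",
                              "".join(rng.choice(list(AA_ALPHABET), size=domain_length)))
               for p in range(n_proteins)]
    D, vocab = build_protein_features([d.seq for d in domains], k_aa=k_aa)

    probes = random_probes(n_probes, seed=seed + 1)
    profiles = profiles_for_probes([p.seq for p in probes], em, fp)
    feats = build_rna_features([p.seq for p in probes], profiles, k=rna_k)
    n_kmers = feats.n_kmers

    # planted W = A0 B0^T over (aa vocab) x (RNA feature space)
    dp = D.shape[1]
    A0 = rng.normal(0.0, 1.0, size=(dp, rank))
    B0 = np.zeros((6 * n_kmers, rank))
    s_col, e_col = 1, 5  # blocks for S and E contexts (after the count block)
    for r in range(rank):
        chosen = rng.integers(0, n_kmers, size=8)
        for code in chosen:
            B0[code, r] += rng.normal(0.0, 1.0)  # count loading
            if structure_loading:
                c = rng.normal(0.0, 2.0)
                B0[e_col * n_kmers + code, r] += c
                B0[s_col * n_kmers + code, r] -= c
    signal = np.asarray((D @ A0) @ (feats.matrix @ B0).T)
    sd = signal.std()
    noise = rng.normal(0.0, noise_sd_frac * (sd if sd > 0 else 1.0),
                       size=signal.shape)
    return ProteinPanel(domains, probes, profiles, signal + noise, feats, D,
                        vocab, planted_signal=signal)
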