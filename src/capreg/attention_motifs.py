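"""Discriminative octamer motifs from attention peaks.

For every classified sample the attention received by each token (final
layer, head-mean, summed over query positions, renormalized) localizes the
regions the model used.  Octamers harvested from the top-attention tokens
+/- a small flank are compared between predicted classes with per-motif
Mann-Whitney U (Wilcoxon rank-sum) tests, and in aggregate against the
full context window.  Candidates below p < 0.01 are exported as a TSV plus
a FASTA of their resident sites, ready for external FIMO/JASPAR scanning.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import LlamaModel
from .training import TokenizedSample, _pad_batch

logger = logging.getLogger(__name__)

__all__ = [
    "AttentionProfile",
    "OctamerCounts",
    "attention_scores",
    "attention_profiles",
    "top_attention_tokens",
    "peak_window_octamers",
    "octamer_count_vectors",
    "normalize_counts",
    "mann_whitney_u",
    "motif_pvalues",
    "aggregate_pvalue",
    "export_candidates",
]

OCTAMER = 8


@dataclass
class AttentionProfile:
    """Per-token attention received, plus spans to map tokens to sequence."""

    predicted_label: int
    scores: np.ndarray  # (n_tokens,), non-negative, sums to 1
    spans: list[tuple[int, int]]
    offsets: list[int]
    sequence: str


def _aggregate_attention(
    probs: np.ndarray, valid: int, head_reduce: str = "mean"
) -> np.ndarray:
    """Attention received per key: reduce heads, sum over queries, renorm.

    Under a causal mask earlier keys are visible to more queries, so even
    uniform attention gives later positions slightly less received mass;
    this bias is shared by all samples and harmless for ranking within one
    sample.
    """
    p = probs[:, :valid, :valid]
    p = p.max(axis=0) if head_reduce == "max" else p.mean(axis=0)
    received = p.sum(axis=0)
    total = received.sum()
    return received / total if total > 0 else received


def attention_scores(
    model: LlamaModel,
    sample: TokenizedSample,
    layer: int = -1,
    head_reduce: str = "mean",
    pad_id: int = 0,
) -> AttentionProfile:
    """Classify one sample and profile its final-layer attention."""
    ids, lens = _pad_batch([sample.ids], pad_id)
    logits = model.forward_cls(ids, lens)
    probs = model.attention_probs()[layer][0]  # (H, T, T)
    scores = _aggregate_attention(probs, len(sample.ids), head_reduce)
    return AttentionProfile(
        predicted_label=int(np.argmax(logits[0])),
        scores=scores,
        spans=list(sample.encoding.spans),
        offsets=list(sample.encoding.offsets),
        sequence=sample.sequence,
    )


def attention_profiles(
    model: LlamaModel,
    samples: list[TokenizedSample],
    batch_size: int = 16,
    layer: int = -1,
    head_reduce: str = "mean",
    pad_id: int = 0,
) -> list[AttentionProfile]:
    """Batched ``attention_scores`` over a dataset."""
    profiles: list[AttentionProfile] = []
    for i in range(0, len(samples), batch_size):
        batch = samples[i : i + batch_size]
        ids, lens = _pad_batch([b.ids for b in batch], pad_id)
        logits = model.forward_cls(ids, lens)
        probs = model.attention_probs()[layer]
        for j, s in enumerate(batch):
            profiles.append(
                AttentionProfile(
                    predicted_label=int(np.argmax(logits[j])),
                    scores=_aggregate_attention(probs[j], len(s.ids), head_reduce),
                    spans=list(s.encoding.spans),
                    offsets=list(s.encoding.offsets),
                    sequence=s.sequence,
                )
            )
    return profiles


def top_attention_tokens(profile: AttentionProfile, n: int = 3) -> list[int]:
    """Indices of the n highest-attention tokens; ties favour the earlier
    token."""
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = np.asarray(profile.scores)
    if n > len(scores):
        warnings.warn(
            f"requested top {n} of {len(scores)} tokens; returning all"
        )
        n = len(scores)
    order = np.argsort(-scores, kind="stable")
    return order[:n].tolist()


def peak_window_octamers(
    sequence: str, token_span: tuple[int, int], flank: int = 5
) -> list[str]:
    """All N-free octamers in [span.start - flank, span.end + flank),
    clipped to the sequence."""
    start = max(0, token_span[0] - flank)
    end = min(len(sequence), token_span[1] + flank)
    window = sequence[start:end]
    return [
        window[i : i + OCTAMER]
        for i in range(max(0, len(window) - OCTAMER + 1))
        if "N" not in window[i : i + OCTAMER]
    ]


@dataclass
class OctamerCounts:
    """Per-sample and aggregate octamer counts, split by predicted class.

    ``*_sample_counts`` hold one Counter per sample (peak windows only);
    ``*_context_counts`` count every octamer of the full window.
    """

    pos_sample_counts: list[Counter] = field(default_factory=list)
    neg_sample_counts: list[Counter] = field(default_factory=list)
    pos_context_counts: Counter = field(default_factory=Counter)
    neg_context_counts: Counter = field(default_factory=Counter)

    @property
    def pos_counts(self) -> Counter:
        return sum(self.pos_sample_counts, Counter())

    @property
    def neg_counts(self) -> Counter:
        return sum(self.neg_sample_counts, Counter())


def octamer_count_vectors(
    profiles: list[AttentionProfile], n_top: int = 3, flank: int = 5
) -> OctamerCounts:
    """Harvest octamers from each sample's top-attention token windows.

    Peak-window counts are kept per sample (the per-motif rank-sum test
    compares these vectors between predicted classes); full-context counts
    are aggregated per class for the peak-vs-context comparison.  Tokens
    are not deduplicated across offsets: each (sample, token) occurrence
    contributes once.
    """
    counts = OctamerCounts()
    for prof in profiles:
        per_sample: Counter = Counter()
        for tok in top_attention_tokens(prof, n_top):
            per_sample.update(
                peak_window_octamers(prof.sequence, prof.spans[tok], flank)
            )
        context = Counter(
            prof.sequence[i : i + OCTAMER]
            for i in range(len(prof.sequence) - OCTAMER + 1)
            if "N" not in prof.sequence[i : i + OCTAMER]
        )
        if prof.predicted_label == 1:
            counts.pos_sample_counts.append(per_sample)
            counts.pos_context_counts.update(context)
        else:
            counts.neg_sample_counts.append(per_sample)
            counts.neg_context_counts.update(context)
    return counts


def normalize_counts(
    pos_counts: dict[str, float], neg_counts: dict[str, float]
) -> tuple[dict[str, float], dict[str, float]]:
    """Scale negative-class counts by R = sum(pos) / sum(neg).

    The positive class is left raw; after scaling both classes have equal
    totals.
    """
    tot_pos = float(sum(pos_counts.values()))
    tot_neg = float(sum(neg_counts.values()))
    if tot_pos <= 0 or tot_neg <= 0:
        raise ValueError("both classes need a positive total count")
    r = tot_pos / tot_neg
    return (
        {k: float(v) for k, v in pos_counts.items()},
        {k: v * r for k, v in neg_counts.items()},
    )


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (two-sided) with midrank tie handling.

    Exact p by enumeration for tie-free samples with n + m <= 12, else the
    normal approximation with tie-corrected variance and continuity
    correction.  Returns (U of the first sample, two-sided p); identical
    constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # no rank information at all
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    # the asymptotic tail can underflow to exactly 0; keep p in (0, 1]
    return float(res.statistic), float(max(res.pvalue, 1e-300))


def motif_pvalues(counts: OctamerCounts, alpha: float = 0.01) -> pd.DataFrame:
    """Per-octamer rank-sum tests between predicted classes.

    Negative-class per-sample count vectors are scaled by the class total
    ratio, then each octamer's vector over positive-class samples is
    tested against its vector over negative-class samples.  The table is
    sorted by ascending p-value; ``flagged`` marks p < alpha, and a
    Benjamini-Hochberg q column is provided alongside the raw filter.
    """
    pos_total = sum(sum(c.values()) for c in counts.pos_sample_counts)
    neg_total = sum(sum(c.values()) for c in counts.neg_sample_counts)
    if pos_total <= 0 or neg_total <= 0:
        raise ValueError("both predicted classes need non-empty peak windows")
    r = pos_total / neg_total
    universe = sorted(
        set().union(*counts.pos_sample_counts, *counts.neg_sample_counts)
    )
    rows = []
    for octamer in universe:
        x = np.array([c.get(octamer, 0) for c in counts.pos_sample_counts], float)
        y = np.array([c.get(octamer, 0) for c in counts.neg_sample_counts], float)
        u, p = mann_whitney_u(x, y * r)
        rows.append(
            {
                "octamer": octamer,
                "pos_count": int(x.sum()),
                "neg_count": int(y.sum()),
                "neg_count_norm": float(y.sum() * r),
                "U": u,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["p_value", "octamer"], kind="stable", ignore_index=True
    )
    m = len(table)
    bh = table["p_value"].to_numpy() * m / (np.arange(m) + 1)
    table["q_value"] = np.minimum.accumulate(bh[::-1])[::-1].clip(max=1.0)
    table["flagged"] = table["p_value"] < alpha
    table["rank"] = np.arange(1, m + 1)
    return table


def aggregate_pvalue(
    peak_counts: dict[str, float], context_counts: dict[str, float]
) -> float:
    """One rank-sum test between normalized frequency vectors.

    Both count dictionaries are projected onto the union of their octamer
    universes, converted to frequencies, and compared as two samples (one
    value per octamer in each group).
    """
    universe = sorted(set(peak_counts) | set(context_counts))
    a = np.array([peak_counts.get(k, 0) for k in universe], float)
    b = np.array([context_counts.get(k, 0) for k in universe], float)
    if a.sum() > 0:
        a = a / a.sum()
    if b.sum() > 0:
        b = b / b.sum()
    if len(universe) < 2:
        return 1.0
    _, p = mann_whitney_u(a, b)
    return p


def export_candidates(
    motif_table: pd.DataFrame,
    profiles: list[AttentionProfile],
    out_prefix: str,
    n_top: int = 3,
    flank: int = 5,
) -> tuple[str, str]:
    """Write flagged motifs as TSV plus a FASTA of their resident sites.

    Each FASTA record is one top-attention-token window (token +/- flank)
    containing a flagged octamer; the header encodes sample index and
    window coordinates (``motif|sample<i>|<start>-<end>``) so sites can be
    traced back.  Suitable as FIMO input.
    """
    flagged = motif_table[motif_table["flagged"]]
    tsv_path = f"{out_prefix}_motifs.tsv"
    fasta_path = f"{out_prefix}_sites.fasta"
    flagged.to_csv(tsv_path, sep="\t", index=False)
    if flagged.empty:
        warnings.warn("no motifs passed the p-value filter; outputs are empty")
    motifs = set(flagged["octamer"])
    with open(fasta_path, "w") as fh:
        for si, prof in enumerate(profiles):
            for tok in top_attention_tokens(prof, n_top):
                start = max(0, prof.spans[tok][0] - flank)
                end = min(len(prof.sequence), prof.spans[tok][1] + flank)
                window = prof.sequence[start:end]
                present = {
                    m
                    for m in motifs
                    if m in window
                }
                for m in sorted(present):
                    fh.write(f">{m}|sample{si}|{start}-{end}\n{window}\n")
    return tsv_path, fasta_path
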