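"""Subsampling analyses: clone overlap between equal-sized subsamples, and
the audit showing why single-cell-only "emergent clone" discovery is biased.

The overlap curve models two hypothetical repeat experiments on the same
specimen: two independent (not disjoint) subsamples of the same cell
population. Its overlap statistic is the Jaccard fraction of the clonotype
sets by default; the asymmetric "fraction of A's clonotypes found in B" is
exposed as an alternative because the underlying quantity ("percentage of
overlapping clones") is ambiguous between the two.

The emergence audit takes clonotypes that look new at a timepoint in
single-cell data (zero cells at all earlier single-cell timepoints) and
checks them against bulk sequencing: a candidate is *corroborated* only when
bulk called it significantly expanded from a baseline productive frequency
below the novelty threshold; otherwise it is a *false emergent* (bulk shows
it was already present, or never significantly expanded)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonodyn.diff_abundance import DiffAbundanceResult
from clonodyn.errors import ConfigError
from clonodyn.repertoire_io import Repertoire

__all__ = ["OverlapCurve", "overlap_curve", "audit_emergent_clones"]


@dataclass
class OverlapCurve:
    """Mean/sd of clone-set overlap between subsample pairs, per size."""

    table: pd.DataFrame  # columns: sample_size, mean_overlap, sd_overlap
    n_reps: int
    seed: int
    denominator: str


def overlap_curve(
    cells,
    sizes,
    n_reps: int = 200,
    seed: int = 0,
    denominator: str = "jaccard",
) -> OverlapCurve:
    """Clonotype overlap between two equal-sized cell subsamples, by size.

    For each size ``s`` and repetition, two subsamples of ``s`` cells are
    drawn independently without replacement (the two draws may share cells);
    overlap is computed on their clonotype *sets*. Cells without a recovered
    TRB are ignored.

    Parameters
    ----------
    cells
        A :class:`~clonodyn.sc_link.SingleCellTable`, or any sequence of
        per-cell clonotype labels.
    """
    if hasattr(cells, "obs"):
        labels = cells.obs.loc[cells.has_trb(), "trb_cdr3_nt"].to_numpy()
    else:
        labels = np.asarray([c for c in cells if c], dtype=object)
    n = labels.size
    sizes = [int(s) for s in sizes]
    if any(s <= 0 for s in sizes):
        raise ConfigError("subsample sizes must be positive")
    if max(sizes) > n:
        raise ConfigError(f"subsample size {max(sizes)} exceeds population of {n} TRB+ cells")
    if denominator not in ("jaccard", "fraction_of_a"):
        raise ConfigError(f"unknown denominator {denominator!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for s in sizes:
        overlaps = np.empty(n_reps)
        for r in range(n_reps):
            a = set(labels[rng.choice(n, size=s, replace=False)])
            b = set(labels[rng.choice(n, size=s, replace=False)])
            inter = len(a & b)
            if denominator == "jaccard":
                overlaps[r] = inter / len(a | b)
            else:
                overlaps[r] = inter / len(a)
        rows.append(
            {
                "sample_size": s,
                "mean_overlap": float(overlaps.mean()),
                "sd_overlap": float(overlaps.std(ddof=1)) if n_reps > 1 else 0.0,
            }
        )
    return OverlapCurve(
        table=pd.DataFrame(rows), n_reps=n_reps, seed=seed, denominator=denominator
    )


def audit_emergent_clones(
    sc_series: dict[str, "object"],
    t: str,
    bulk_diff: DiffAbundanceResult,
    bulk_baseline: Repertoire,
    novelty_max: float = 0.001,
    timepoint_order=None,
) -> pd.DataFrame:
    """Audit clonotypes that appear "emergent" in single-cell data at ``t``.

    Candidates have at least one TRB+ cell at ``t`` and zero cells at every
    earlier single-cell timepoint. Each is checked against the bulk
    baseline productive frequency and the bulk differential-abundance call
    at ``t``; the verdict is ``corroborated`` iff bulk flagged the clone
    significantly expanded AND its bulk baseline frequency is strictly below
    the novelty threshold, else ``false_emergent``.

    Returns one row per candidate with columns ``trb_cdr3_nt,
    detected_cells_at_t, bulk_baseline_frequency, bulk_significant,
    verdict`` plus a ``false_emergent_fraction`` in ``DataFrame.attrs``.
    """
    from clonodyn.repertoire_io import DEFAULT_TIMEPOINT_ORDER

    order = list(timepoint_order or DEFAULT_TIMEPOINT_ORDER)
    if t not in sc_series:
        raise ConfigError(f"timepoint {t!r} not in single-cell series")
    for tp in sc_series:
        if tp not in order:
            raise ConfigError(f"unknown timepoint {tp!r}; allowed: {order}")

    def clonotype_counts(cells) -> pd.Series:
        obs = cells.obs
        return obs.loc[obs["trb_cdr3_nt"].fillna("") != "", "trb_cdr3_nt"].value_counts()

    at_t = clonotype_counts(sc_series[t])
    earlier = [tp for tp in sc_series if order.index(tp) < order.index(t)]
    if not earlier:
        raise ConfigError(f"no single-cell timepoints earlier than {t!r}")
    seen_earlier: set[str] = set()
    for tp in earlier:
        seen_earlier.update(clonotype_counts(sc_series[tp]).index)
    candidates = sorted(set(at_t.index) - seen_earlier)

    # bulk significance by CDR3 nucleotide (the single-cell match level)
    rec = bulk_diff.records
    expanded_nt = set(rec.loc[rec["class"] == "expanded", "cdr3_nt"])
    baseline_freq_by_nt: dict[str, float] = {}
    total = bulk_baseline.total_productive_templates
    for key, clone in bulk_baseline.clones.items():
        if clone.productive:
            baseline_freq_by_nt[key.cdr3_nt] = (
                baseline_freq_by_nt.get(key.cdr3_nt, 0.0) + clone.templates / total
            )

    rows = []
    for nt in candidates:
        f0 = baseline_freq_by_nt.get(nt, 0.0)
        significant = nt in expanded_nt
        verdict = "corroborated" if (significant and f0 < novelty_max) else "false_emergent"
        rows.append(
            {
                "trb_cdr3_nt": nt,
                "detected_cells_at_t": int(at_t[nt]),
                "bulk_baseline_frequency": f0,
                "bulk_significant": significant,
                "verdict": verdict,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "trb_cdr3_nt", "detected_cells_at_t", "bulk_baseline_frequency",
            "bulk_significant", "verdict",
        ],
    )
    out.attrs["false_emergent_fraction"] = (
        float((out["verdict"] == "false_emergent").mean()) if len(out) else float("nan")
    )
    return out
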