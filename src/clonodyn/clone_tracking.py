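"""Per-clone trajectories across timepoints/compartments, temporal
association of novel expansions with clinical events, and bone-marrow /
peripheral-blood expansion concordance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from clonodyn.diff_abundance import DiffAbundanceResult
from clonodyn.errors import ConfigError, UndefinedStatisticError
from clonodyn.repertoire_io import (
    DEFAULT_TIMEPOINT_ORDER,
    CloneKey,
    Repertoire,
    productive_frequency,
)

__all__ = [
    "CloneTrajectory",
    "EventAssociation",
    "build_trajectories",
    "event_association",
    "compartment_concordance",
]


@dataclass
class CloneTrajectory:
    """One clonotype's frequency path with per-comparison significance.

    ``frequencies`` maps (timepoint, compartment) -> productive frequency
    (0.0 where the clone is absent); ``classes`` maps (timepoint,
    compartment) -> expanded/contracted/unchanged versus baseline.
    """

    key: CloneKey
    frequencies: dict[tuple[str, str], float] = field(default_factory=dict)
    classes: dict[tuple[str, str], str] = field(default_factory=dict)
    first_significant_timepoint: str | None = None
    transient: bool = False  # significant then back to unchanged/contracted


def _tp_rank(tp: str, order) -> int:
    try:
        return order.index(tp)
    except ValueError:
        raise ConfigError(f"unknown timepoint {tp!r}; allowed: {list(order)}")


def build_trajectories(
    repertoires: dict[tuple[str, str], Repertoire],
    diff_results: list[DiffAbundanceResult],
    baseline: str = "Day0",
    timepoint_order=DEFAULT_TIMEPOINT_ORDER,
) -> list[CloneTrajectory]:
    """Assemble trajectories for clones novel-expanded in any comparison.

    Parameters
    ----------
    repertoires
        Mapping (timepoint, compartment) -> Repertoire for one subject.
    diff_results
        Baseline-vs-timepoint comparisons (one per timepoint/compartment).
    """
    order = list(timepoint_order)
    if not any(tp == baseline for tp, _ in repertoires):
        raise ConfigError(f"baseline timepoint {baseline!r} missing from series")
    selected: set[CloneKey] = set()
    for res in diff_results:
        selected.update(res.novel_expanded_keys())
    trajectories = []
    for key in sorted(selected):
        traj = CloneTrajectory(key=key)
        for (tp, comp), rep in sorted(repertoires.items()):
            traj.frequencies[(tp, comp)] = (
                productive_frequency(rep, key) if rep.total_productive_templates else 0.0
            )
        sig_tps = []
        for res in diff_results:
            sub = res.records[
                (res.records["cdr3_nt"] == key.cdr3_nt)
                & (res.records["v_gene"] == key.v_gene)
                & (res.records["j_gene"] == key.j_gene)
            ]
            cls = sub["class"].iloc[0] if len(sub) else "unchanged"
            traj.classes[(res.timepoint2, res.compartment)] = cls
            if cls != "unchanged":
                sig_tps.append(res.timepoint2)
        if sig_tps:
            traj.first_significant_timepoint = min(sig_tps, key=lambda t: _tp_rank(t, order))
            # transient: class reverts at a later sampled timepoint
            last_sig = max(sig_tps, key=lambda t: _tp_rank(t, order))
            later = [
                cls
                for (tp, _c), cls in traj.classes.items()
                if _tp_rank(tp, order) > _tp_rank(last_sig, order)
            ]
            traj.transient = bool(later) and all(c != "expanded" for c in later)
        trajectories.append(traj)
    return trajectories


@dataclass
class EventAssociation:
    """Partition of significant clones around a clinical event timepoint."""

    event_label: str
    event_timepoint: str
    clones_at_event: list[CloneKey]
    clones_preceding: list[CloneKey]
    clones_following: list[CloneKey]

    @property
    def n_preceding(self) -> int:
        return len(self.clones_preceding)


def event_association(
    trajectories: list[CloneTrajectory],
    event_timepoint: str,
    event_label: str = "",
    timepoint_order=DEFAULT_TIMEPOINT_ORDER,
) -> EventAssociation:
    """Partition significant clones by first-significant timepoint relative
    to a clinical event (e.g. an irAE diagnosis).

    The partition (preceding / at-event / following) is exhaustive and
    disjoint over trajectories with a significant timepoint.
    """
    order = list(timepoint_order)
    ev = _tp_rank(event_timepoint, order)
    at, before, after = [], [], []
    for traj in trajectories:
        if traj.first_significant_timepoint is None:
            continue
        r = _tp_rank(traj.first_significant_timepoint, order)
        if r == ev:
            at.append(traj.key)
        elif r < ev:
            before.append(traj.key)
        else:
            after.append(traj.key)
    return EventAssociation(
        event_label=event_label,
        event_timepoint=event_timepoint,
        clones_at_event=at,
        clones_preceding=before,
        clones_following=after,
    )


def compartment_concordance(
    bm_result: DiffAbundanceResult,
    pb_result: DiffAbundanceResult,
    n_permutations: int = 10000,
    seed: int = 0,
) -> dict:
    """Concordance of expansion magnitude between compartments at one
    timepoint.

    For clones significant in either compartment, pairs (log2 fold BM,
    log2 fold PB) are correlated by Spearman rank correlation; the two-sided
    p-value comes from seeded label permutations (rank-based statistics on
    heavy-tailed folds).

    Raises
    ------
    UndefinedStatisticError
        with a reason when fewer than 3 paired clones are significant.
    """
    key_cols = ["cdr3_nt", "v_gene", "j_gene"]
    bm = bm_result.records.set_index(key_cols)
    pb = pb_result.records.set_index(key_cols)
    sig = sorted(
        set(bm.index[bm["class"] != "unchanged"]) | set(pb.index[pb["class"] != "unchanged"])
    )
    paired = [k for k in sig if k in bm.index and k in pb.index]
    if len(paired) < 3:
        raise UndefinedStatisticError(
            f"only {len(paired)} paired significant clones (need >= 3)"
        )
    x = bm.loc[paired, "log2_fold"].to_numpy()
    y = pb.loc[paired, "log2_fold"].to_numpy()
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    perm_rho = np.empty(n_permutations)
    yr = pd.Series(y).rank().to_numpy()
    xr = pd.Series(x).rank().to_numpy()
    xr_c = xr - xr.mean()
    denom = np.sqrt((xr_c**2).sum())
    for i in range(n_permutations):
        ys = rng.permutation(yr)
        ys_c = ys - ys.mean()
        perm_rho[i] = (xr_c @ ys_c) / (denom * np.sqrt((ys_c**2).sum()))
    p = float((np.sum(np.abs(perm_rho) >= abs(rho) - 1e-12) + 1) / (n_permutations + 1))
    return {
        "n_clones": len(paired),
        "spearman_rho": rho,
        "permutation_p": p,
        "pairs": pd.DataFrame(
            {"log2_fold_1": x, "log2_fold_2": y},
            index=pd.MultiIndex.from_tuples(paired, names=key_cols),
        ),
    }
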