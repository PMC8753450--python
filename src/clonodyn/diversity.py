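"""Repertoire diversity: richness, Shannon entropy, and normalized clonality.

Clonality is the immunosequencing-industry normalization
``1 - H / ln(R)`` with H the Shannon entropy in nats and R the clone
richness: 0 for a maximally even repertoire, 1 for a monoclonal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from clonodyn.errors import UndefinedStatisticError
from clonodyn.repertoire_io import Repertoire

__all__ = ["DiversityResult", "clonality", "repertoire_clonality", "subset_clonality"]


@dataclass(frozen=True)
class DiversityResult:
    richness: int
    entropy_nats: float
    clonality: float
    n_templates: int


def clonality(counts) -> DiversityResult:
    """Shannon entropy and normalized clonality of a count vector.

    ``p_i = c_i / sum(c)``; ``H = -sum p_i ln p_i``;
    ``clonality = 1 - H/ln(R)`` for richness R >= 2. A single-clone sample is
    fully monoclonal by convention (clonality 1, H = 0).

    Raises
    ------
    UndefinedStatisticError
        on an empty or all-zero count vector.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise UndefinedStatisticError("clonality undefined on empty or all-zero counts")
    n = c.sum()
    p = c / n
    h = float(-np.sum(p * np.log(p)))
    r = int(c.size)
    if r == 1:
        clon = 1.0
    else:
        clon = 1.0 - h / np.log(r)
        clon = min(max(clon, 0.0), 1.0)
    return DiversityResult(richness=r, entropy_nats=h, clonality=float(clon), n_templates=int(n))


def repertoire_clonality(rep: Repertoire) -> DiversityResult:
    """Clonality of a bulk repertoire over productive clones only."""
    counts = list(rep.productive_counts().values())
    return clonality(counts)


def subset_clonality(
    cells,
    subset_column: str = "subset",
    clonotype_column: str = "trb_cdr3_nt",
    min_cells: int = 20,
) -> dict[str, DiversityResult | None]:
    """Per-subset clonality of a gated single-cell table.

    Counts are *cells per clonotype* within each subset (one cell = one T
    cell, the single-cell analogue of a bulk template). Cells without a
    recovered TRB chain are excluded. Subsets with fewer than ``min_cells``
    TRB-bearing cells are reported as ``None`` (undefined).

    Parameters
    ----------
    cells
        A :class:`~clonodyn.sc_link.SingleCellTable` or its ``obs`` DataFrame.
    """
    obs = getattr(cells, "obs", cells)
    has_trb = obs[clonotype_column].fillna("") != ""
    out: dict[str, DiversityResult | None] = {}
    for subset, grp in obs[has_trb].groupby(subset_column, sort=True):
        if subset == "unassigned":
            continue
        if len(grp) < min_cells:
            out[str(subset)] = None
            continue
        counts = grp[clonotype_column].value_counts().to_numpy()
        out[str(subset)] = clonality(counts)
    return out
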