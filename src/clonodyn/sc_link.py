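"""Single-cell layer: ADT gating, bulk-to-single-cell clonotype linkage,
supervised differential signatures, module scores, and clone phenotype
stability.

Gating is cytometry-style: each marker gets a cutoff on log1p-transformed
raw ADT counts; positive/negative calls feed fixed subset rules (CD4 vs CD8
among CD3+; naive / central-memory / effector-memory / terminal-effector by
CCR7 x CD45RA; CD4+CD127loCD25hi regulatory T cells override the CD4 memory
labels). "auto" derives per-marker cutoffs by two-component (Otsu)
separation and takes the median across a subject's samples as consensus.

Differential signatures use per-cell two-sided Wilcoxon rank-sum tests with
Bonferroni correction over *all* features of the tested modality; gene
expression is counts-per-10,000 log1p normalized and ADT is centered-log-
ratio transformed per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.stats import mannwhitneyu

from clonodyn.errors import ConfigError, UndefinedStatisticError
from clonodyn.repertoire_io import CloneKey, Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "SingleCellTable",
    "GatingScheme",
    "REQUIRED_GATING_MARKERS",
    "otsu_threshold",
    "auto_gating_scheme",
    "gate_subsets",
    "subset_frequencies",
    "percent_change",
    "link_bulk_clones",
    "top_abundant_comparator",
    "differential_signature",
    "module_score",
    "clone_phenotype_composition",
    "cp10k_log1p",
    "clr_adt",
    "read_vdj_contigs",
    "read_single_cell_inputs",
    "write_single_cell_inputs",
    "load_gene_set",
]

REQUIRED_GATING_MARKERS = ("CD3", "CD4", "CD8", "CCR7", "CD45RA", "CD127", "CD25")

T_SUBSETS = (
    "CD4_naive", "CD4_CM", "CD4_EM", "CD4_TE", "Treg",
    "CD8_naive", "CD8_CM", "CD8_EM", "CD8_TE",
)


@dataclass
class SingleCellTable:
    """Per-cell clonotype + ADT counts + gene counts for one sample.

    ``obs`` is indexed by unique cell barcode with columns ``trb_cdr3_nt``,
    ``trb_cdr3_aa``, ``trb_v_gene``, ``trb_j_gene``, ``tra_cdr3_aa`` (empty
    string where the chain was not recovered) and ``subset`` (assigned by
    gating, initially "unassigned"). ``adt`` is cells x markers raw counts;
    ``gene_counts`` is a cells x genes sparse non-negative integer matrix.
    """

    obs: pd.DataFrame
    adt: pd.DataFrame
    gene_counts: sparse.spmatrix
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.obs.index.is_unique:
            raise ValueError("cell barcodes must be unique")
        if not self.obs.index.equals(self.adt.index):
            raise ValueError("obs and adt must share the same barcode index")
        if self.gene_counts.shape != (len(self.obs), len(self.genes)):
            raise ValueError(
                f"gene_counts shape {self.gene_counts.shape} != "
                f"({len(self.obs)}, {len(self.genes)})"
            )
        if "subset" not in self.obs.columns:
            self.obs["subset"] = "unassigned"

    @property
    def n_cells(self) -> int:
        return len(self.obs)

    @property
    def markers(self) -> list[str]:
        return list(self.adt.columns)

    def has_trb(self) -> pd.Series:
        return self.obs["trb_cdr3_nt"].fillna("") != ""


@dataclass
class GatingScheme:
    """Per-marker cutoffs on log1p-transformed ADT counts."""

    cutoffs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, c in self.cutoffs.items():
            if c <= 0:
                raise ValueError(f"cutoff for {m} must be positive, got {c}")


def otsu_threshold(values) -> float:
    """Two-component separation threshold: maximize between-class variance.

    Exact over the sorted sample (no histogram binning); ties broken toward
    the lower threshold so the result is deterministic.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise ValueError("need at least two distinct values")
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(1, n)  # lower class sizes
    mu1 = csum[:-1] / k
    mu2 = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mu1 - mu2) ** 2
    # exclude splits between equal values (threshold would be degenerate)
    valid = x[1:] > x[:-1]
    between[~valid] = -np.inf
    i = int(np.argmax(between))
    return float((x[i] + x[i + 1]) / 2.0)


def auto_gating_scheme(tables, markers=REQUIRED_GATING_MARKERS) -> GatingScheme:
    """Consensus auto cutoffs: per-marker Otsu on log1p counts, median across
    the given samples of one subject."""
    if isinstance(tables, SingleCellTable):
        tables = [tables]
    cutoffs: dict[str, float] = {}
    for m in markers:
        per_sample = []
        for t in tables:
            if m not in t.adt.columns:
                raise ConfigError(f"required gating marker {m!r} missing from ADT panel")
            per_sample.append(otsu_threshold(np.log1p(t.adt[m].to_numpy())))
        cutoffs[m] = float(np.median(per_sample))
    return GatingScheme(cutoffs=cutoffs)


def gate_subsets(cells: SingleCellTable, scheme: GatingScheme | str = "auto") -> SingleCellTable:
    """Assign every cell exactly one subset label (or "unassigned").

    Rules on thresholded positive/negative marker calls: CD3+ is required;
    CD4+ and CD8+ are mutually exclusive (double-positive or double-negative
    cells stay unassigned); memory state from CCR7 x CD45RA (naive +/+, CM
    +/-, EM -/-, TE -/+); CD4+ CD127-low CD25-high cells are relabelled Treg
    regardless of memory state. Modifies ``cells.obs["subset"]`` in place
    and returns the table.
    """
    if isinstance(scheme, str):
        if scheme != "auto":
            raise ConfigError(f"unknown scheme {scheme!r}")
        scheme = auto_gating_scheme(cells)
    missing = [m for m in REQUIRED_GATING_MARKERS if m not in scheme.cutoffs]
    if missing:
        raise ConfigError(f"gating scheme missing cutoffs for: {', '.join(missing)}")
    missing_panel = [m for m in REQUIRED_GATING_MARKERS if m not in cells.adt.columns]
    if missing_panel:
        raise ConfigError(f"ADT panel missing required marker(s): {', '.join(missing_panel)}")
    log_adt = np.log1p(cells.adt[list(REQUIRED_GATING_MARKERS)].to_numpy(float))
    pos = {
        m: log_adt[:, j] > scheme.cutoffs[m] for j, m in enumerate(REQUIRED_GATING_MARKERS)
    }
    n = cells.n_cells
    labels = np.full(n, "unassigned", dtype=object)
    cd3 = pos["CD3"]
    cd4 = pos["CD4"] & ~pos["CD8"]
    cd8 = pos["CD8"] & ~pos["CD4"]
    state = np.where(
        pos["CCR7"],
        np.where(pos["CD45RA"], "naive", "CM"),
        np.where(pos["CD45RA"], "TE", "EM"),
    )
    for lineage, mask in (("CD4", cd3 & cd4), ("CD8", cd3 & cd8)):
        labels[mask] = np.char.add(f"{lineage}_", state[mask].astype(str))
    treg = cd3 & cd4 & ~pos["CD127"] & pos["CD25"]
    labels[treg] = "Treg"
    cells.obs["subset"] = labels
    return cells


def subset_frequencies(cells: SingleCellTable) -> pd.Series:
    """Subset fractions among *assigned* CD3+ cells (unassigned excluded,
    fractions renormalized over assigned cells; sums to 1)."""
    assigned = cells.obs["subset"][cells.obs["subset"] != "unassigned"]
    if assigned.empty:
        raise UndefinedStatisticError("no gated cells: run gate_subsets first")
    freqs = assigned.value_counts(normalize=True).sort_index()
    freqs.name = "fraction_of_assigned_cd3"
    return freqs


def percent_change(f0: pd.Series, ft: pd.Series) -> pd.Series:
    """Per-subset percent change ``100 * (f_t - f_0) / f_0``; NaN where the
    baseline fraction is zero (undefined)."""
    subsets = f0.index.union(ft.index)
    f0 = f0.reindex(subsets, fill_value=0.0)
    ft = ft.reindex(subsets, fill_value=0.0)
    out = pd.Series(np.where(f0 > 0, 100.0 * (ft - f0) / f0.replace(0, np.nan), np.nan),
                    index=subsets, name="percent_change")
    return out


def _lineage(subset: str) -> str | None:
    if subset == "Treg" or subset.startswith("CD4"):
        return "CD4"
    if subset.startswith("CD8"):
        return "CD8"
    return None


def link_bulk_clones(
    cells: SingleCellTable,
    bulk_keys,
    bulk: Repertoire | None = None,
    min_cells: int = 5,
) -> dict[CloneKey, dict]:
    """Map bulk-identified clones to single-cell barcode sets.

    Matching is on the CDR3beta nucleotide junction; when a key has no
    nucleotide match and the bulk repertoire is supplied, matching falls
    back to (CDR3beta amino acid, V gene) with a logged downgrade. Clones
    with fewer than ``min_cells`` matched cells are returned but flagged
    ``under_covered`` (excluded from differential analyses by default).
    Empty matches are allowed.
    """
    nt = cells.obs["trb_cdr3_nt"].fillna("")
    aa_v = pd.Series(
        list(zip(cells.obs["trb_cdr3_aa"].fillna(""), cells.obs["trb_v_gene"].fillna(""))),
        index=cells.obs.index,
    )
    out: dict[CloneKey, dict] = {}
    for key in bulk_keys:
        barcodes = cells.obs.index[nt == key.cdr3_nt]
        level = "nt"
        if len(barcodes) == 0 and bulk is not None and key in bulk.clones:
            aa = bulk.clones[key].cdr3_aa
            if aa:
                barcodes = cells.obs.index[aa_v == (aa, key.v_gene)]
                if len(barcodes):
                    level = "aa_v"
                    logger.warning(
                        "clone %s matched at amino-acid+V level only", key.cdr3_nt
                    )
        out[key] = {
            "barcodes": list(barcodes),
            "n_cells": len(barcodes),
            "under_covered": len(barcodes) < min_cells,
            "match_level": level if len(barcodes) else "none",
        }
    return out


def top_abundant_comparator(
    cells: SingleCellTable,
    bulk_rep: Repertoire,
    clones_of_interest=(),
    k: int = 10,
    lineage: str = "CD8",
    min_cells: int = 5,
) -> tuple[list[CloneKey], list[str]]:
    """The comparator group: cells of the ``k`` most abundant bulk clones of
    the requested lineage, excluding the clones of interest.

    Bulk clones are ranked by template count (ties broken by lexicographic
    CDR3 nucleotide); a clone qualifies when the majority of its linked,
    gated cells belong to the requested lineage. Returns (selected keys,
    their cell barcodes).
    """
    interest = set(clones_of_interest)
    ranked = sorted(
        bulk_rep.productive_counts().items(), key=lambda kv: (-kv[1], kv[0].cdr3_nt)
    )
    linkage = link_bulk_clones(
        cells, [key for key, _ in ranked], bulk=bulk_rep, min_cells=min_cells
    )
    selected: list[CloneKey] = []
    barcodes: list[str] = []
    for key, _count in ranked:
        if len(selected) == k:
            break
        if key in interest:
            continue
        info = linkage[key]
        if info["n_cells"] == 0 or info["under_covered"]:
            continue
        lineages = [
            _lineage(cells.obs.loc[b, "subset"]) for b in info["barcodes"]
        ]
        n_match = sum(1 for x in lineages if x == lineage)
        if n_match * 2 <= len(lineages):
            continue
        selected.append(key)
        barcodes.extend(info["barcodes"])
    if len(selected) < k:
        logger.warning("only %d eligible comparator clones (requested %d)", len(selected), k)
    return selected, barcodes


def cp10k_log1p(gene_counts: sparse.spmatrix) -> np.ndarray:
    """Counts-per-10,000 + log1p normalization, densified."""
    x = np.asarray(gene_counts.todense(), dtype=float)
    lib = x.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(x / lib * 1e4)


def clr_adt(adt: pd.DataFrame) -> pd.DataFrame:
    """Centered-log-ratio transform per cell across the ADT panel."""
    logx = np.log1p(adt.to_numpy(float))
    return pd.DataFrame(
        logx - logx.mean(axis=1, keepdims=True), index=adt.index, columns=adt.columns
    )


def _tier(p_adj: np.ndarray) -> np.ndarray:
    return np.where(p_adj < 0.01, "**", np.where(p_adj < 0.05, "*", "."))


def differential_signature(
    cells: SingleCellTable,
    group_barcodes,
    comparator_barcodes,
    features: str = "genes",
    min_cells: int = 5,
) -> pd.DataFrame:
    """Supervised per-feature signature of a cell group versus a comparator.

    Two-sided Wilcoxon rank-sum test per feature, Bonferroni-corrected by
    the *total* number of features of the modality (all genes, or all panel
    proteins). Returns one row per feature with group means (normalized
    scale), log fold change (difference of log-scale means), statistic, p,
    adjusted p, and significance tier (``**`` adj p < 0.01, ``*`` adj p <
    0.05, ``.`` otherwise), ordered by adjusted p then |logFC|.
    """
    a_idx = cells.obs.index.get_indexer(pd.Index(group_barcodes))
    b_idx = cells.obs.index.get_indexer(pd.Index(comparator_barcodes))
    if (a_idx < 0).any() or (b_idx < 0).any():
        raise ValueError("unknown barcodes in group definitions")
    if len(a_idx) < min_cells or len(b_idx) < min_cells:
        raise UndefinedStatisticError(
            f"both groups need >= {min_cells} cells "
            f"(got {len(a_idx)} and {len(b_idx)})"
        )
    if features == "genes":
        mat = cp10k_log1p(cells.gene_counts)
        names = list(cells.genes)
    elif features == "proteins":
        mat = clr_adt(cells.adt).to_numpy()
        names = list(cells.adt.columns)
    else:
        raise ValueError("features must be 'genes' or 'proteins'")
    xa = mat[a_idx]
    xb = mat[b_idx]
    with np.errstate(invalid="ignore"):
        res = mannwhitneyu(xa, xb, axis=0, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    # constant features (all ties) yield NaN p under the asymptotic normal
    p = np.where(np.isnan(p), 1.0, p)
    m = len(names)
    p_adj = np.minimum(p * m, 1.0)
    mean_a = xa.mean(axis=0)
    mean_b = xb.mean(axis=0)
    out = pd.DataFrame(
        {
            "feature": names,
            "mean_group": mean_a,
            "mean_comparator": mean_b,
            "log_fc": mean_a - mean_b,
            "statistic": np.asarray(res.statistic, dtype=float),
            "p_value": p,
            "p_adjusted": p_adj,
            "tier": _tier(p_adj),
        }
    )
    out = out.sort_values(
        ["p_adjusted", "log_fc"], key=lambda s: s if s.name == "p_adjusted" else -s.abs()
    ).reset_index(drop=True)
    return out


def clone_mean_matrix(
    cells: SingleCellTable, clone_cells: dict, features: str = "genes", feature_names=None
) -> pd.DataFrame:
    """Per-clone mean expression matrix (clones x features) for heatmap
    export, on the normalized scale used by :func:`differential_signature`."""
    if features == "genes":
        mat = cp10k_log1p(cells.gene_counts)
        names = list(cells.genes)
    else:
        mat = clr_adt(cells.adt).to_numpy()
        names = list(cells.adt.columns)
    cols = [names.index(f) for f in feature_names] if feature_names is not None else None
    rows = {}
    for key, info in clone_cells.items():
        barcodes = info["barcodes"] if isinstance(info, dict) else list(info)
        idx = cells.obs.index.get_indexer(pd.Index(barcodes))
        sub = mat[idx]
        rows[key.cdr3_nt if isinstance(key, CloneKey) else str(key)] = (
            sub[:, cols].mean(axis=0) if cols is not None else sub.mean(axis=0)
        )
    return pd.DataFrame(
        rows, index=feature_names if feature_names is not None else names
    ).T


def module_score(
    cells: SingleCellTable,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-module score: mean normalized expression of the module
    genes minus the mean of a matched control set.

    Control genes are drawn (seeded) from expression-matched bins: all genes
    are ranked by dataset-average normalized expression and cut into
    ``n_bins`` equal-size bins; each module gene contributes ``n_ctrl``
    sampled control genes from its own bin. Module genes absent from the
    dataset are dropped with a warning.
    """
    gene_index = {g: i for i, g in enumerate(cells.genes)}
    present = [g for g in gene_set if g in gene_index]
    dropped = [g for g in gene_set if g not in gene_index]
    if dropped:
        logger.warning("dropping %d module genes absent from dataset: %s", len(dropped), dropped)
    if not present:
        raise ConfigError("no module genes present in the dataset")
    mat = cp10k_log1p(cells.gene_counts)
    avg = mat.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(cells.genes), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    module_idx = [gene_index[g] for g in present]
    for gi in module_idx:
        pool = np.nonzero(bin_of == bin_of[gi])[0]
        take = rng.choice(pool, size=min(n_ctrl, pool.size), replace=False)
        ctrl.update(int(t) for t in take)
    ctrl -= set(module_idx)
    if not ctrl:
        raise ConfigError("control gene pool is empty")
    score = mat[:, module_idx].mean(axis=1) - mat[:, sorted(ctrl)].mean(axis=1)
    return pd.Series(score, index=cells.obs.index, name="module_score")


def clone_phenotype_composition(
    tables: dict[str, SingleCellTable],
    clone_keys,
    baseline: str = "Day0",
    min_cells: int = 5,
) -> pd.DataFrame:
    """Per-clone subset composition per timepoint and a stability metric.

    For each clone with at least ``min_cells`` gated cells at every
    timepoint, computes its composition vector over subsets and the
    stability statistic: max over non-baseline timepoints of the total-
    variation distance from the baseline composition (0 = identical
    phenotype mix, 1 = complete switch). Under-covered clones are reported
    with ``evaluable=False`` and NaN stability.
    """
    if baseline not in tables:
        raise ConfigError(f"baseline timepoint {baseline!r} missing")
    rows = []
    for key in clone_keys:
        nt = key.cdr3_nt if isinstance(key, CloneKey) else str(key)
        comps: dict[str, pd.Series] = {}
        evaluable = True
        for tp, cells in tables.items():
            sub = cells.obs[(cells.obs["trb_cdr3_nt"] == nt)]
            sub = sub[sub["subset"] != "unassigned"]
            if len(sub) < min_cells:
                evaluable = False
                break
            comps[tp] = sub["subset"].value_counts(normalize=True)
        if not evaluable:
            rows.append({"cdr3_nt": nt, "evaluable": False, "stability": np.nan})
            continue
        base = comps[baseline]
        tv_max = 0.0
        for tp, comp in comps.items():
            if tp == baseline:
                continue
            subsets = base.index.union(comp.index)
            tv = 0.5 * float(
                np.abs(
                    base.reindex(subsets, fill_value=0.0).to_numpy()
                    - comp.reindex(subsets, fill_value=0.0).to_numpy()
                ).sum()
            )
            tv_max = max(tv_max, tv)
        row = {"cdr3_nt": nt, "evaluable": True, "stability": tv_max}
        for tp, comp in comps.items():
            for s, frac in comp.items():
                row[f"{tp}:{s}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: 10x-style inputs and TSV outputs
# ---------------------------------------------------------------------------

CONTIG_COLUMNS = ("barcode", "chain", "cdr3", "cdr3_nt", "v_gene", "j_gene", "productive")


def read_vdj_contigs(path) -> pd.DataFrame:
    """Read a 10x-style filtered contig CSV and collapse to one row per cell.

    Keeps productive TRB contigs (first per barcode) for the clonotype
    fields and the first productive TRA CDR3 amino-acid sequence.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"contig file missing column(s): {', '.join(missing)}")
    prod = df[df["productive"].str.lower().isin({"true", "t", "1"})]
    trb = prod[prod["chain"] == "TRB"].drop_duplicates("barcode", keep="first")
    tra = prod[prod["chain"] == "TRA"].drop_duplicates("barcode", keep="first")
    out = trb.set_index("barcode")[["cdr3_nt", "cdr3", "v_gene", "j_gene"]].rename(
        columns={
            "cdr3_nt": "trb_cdr3_nt",
            "cdr3": "trb_cdr3_aa",
            "v_gene": "trb_v_gene",
            "j_gene": "trb_j_gene",
        }
    )
    out["tra_cdr3_aa"] = tra.set_index("barcode")["cdr3"]
    return out.fillna("")


def read_single_cell_inputs(gex_mtx, features_tsv, barcodes_tsv, adt_tsv, vdj_csv) -> SingleCellTable:
    """Assemble a SingleCellTable from standard exported files.

    GEX: Matrix-Market (genes x cells or cells x genes, oriented by the
    barcode count) + features/barcodes TSVs; ADT: TSV of cells x markers
    with a barcode index column; VDJ: filtered contig CSV.
    """
    barcodes = pd.read_csv(barcodes_tsv, sep="\t", header=None)[0].astype(str).tolist()
    genes = pd.read_csv(features_tsv, sep="\t", header=None)[0].astype(str).tolist()
    x = sparse.csr_matrix(mmread(gex_mtx))
    if x.shape == (len(genes), len(barcodes)) and x.shape[0] != x.shape[1]:
        x = x.T.tocsr()
    if x.shape != (len(barcodes), len(genes)):
        raise ConfigError(
            f"GEX matrix shape {x.shape} does not match "
            f"{len(barcodes)} barcodes x {len(genes)} features"
        )
    adt = pd.read_csv(adt_tsv, sep="\t", index_col=0)
    adt.index = adt.index.astype(str)
    adt = adt.reindex(barcodes).fillna(0).astype(int)
    vdj = read_vdj_contigs(vdj_csv)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    for col in ("trb_cdr3_nt", "trb_cdr3_aa", "trb_v_gene", "trb_j_gene", "tra_cdr3_aa"):
        obs[col] = vdj[col].reindex(barcodes).fillna("") if col in vdj.columns else ""
    obs["subset"] = "unassigned"
    return SingleCellTable(obs=obs, adt=adt, gene_counts=x, genes=genes)


def write_single_cell_inputs(cells: SingleCellTable, outdir) -> None:
    """Write a table back to the standard input formats (for pipelines and
    round-trip tests): matrix.mtx, features.tsv, barcodes.tsv, adt.tsv,
    contigs.csv."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(cells.gene_counts.T))
    pd.Series(cells.genes).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(cells.obs.index).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    cells.adt.to_csv(outdir / "adt.tsv", sep="\t")
    rows = []
    for barcode, row in cells.obs.iterrows():
        if row["trb_cdr3_nt"]:
            rows.append(
                {
                    "barcode": barcode,
                    "chain": "TRB",
                    "cdr3": row["trb_cdr3_aa"],
                    "cdr3_nt": row["trb_cdr3_nt"],
                    "v_gene": row["trb_v_gene"],
                    "j_gene": row["trb_j_gene"],
                    "productive": "True",
                }
            )
        if row.get("tra_cdr3_aa"):
            rows.append(
                {
                    "barcode": barcode,
                    "chain": "TRA",
                    "cdr3": row["tra_cdr3_aa"],
                    "cdr3_nt": "",
                    "v_gene": "",
                    "j_gene": "",
                    "productive": "True",
                }
            )
    pd.DataFrame(rows, columns=list(CONTIG_COLUMNS)).to_csv(
        outdir / "contigs.csv", index=False
    )


def load_gene_set(name_or_path) -> list[str]:
    """Load a gene set: one symbol per line, '#' comments allowed. Bundled
    sets (``cytotoxicity``, ``exhaustion``, ``naive``) resolve by name."""
    from importlib.resources import files
    from pathlib import Path

    p = Path(str(name_or_path))
    if not p.exists():
        resource = files("clonodyn") / "resources" / "gene_sets" / f"{name_or_path}.txt"
        if not resource.is_file():
            raise ConfigError(f"unknown gene set {name_or_path!r}")
        text = resource.read_text()
    else:
        text = p.read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
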