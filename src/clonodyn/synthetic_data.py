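"""Ground-truth generators for every pipeline stage.

Bulk side: longitudinal repertoire series with a heavy-tailed clone-size
law, beta-binomial between-sample noise at a controlled dispersion, and
spiked clonal expansions (existing clones multiplied, or novel clones
entering from zero baseline) with known fold changes.

Single-cell side: cell tables with subset-structured ADT counts
(negative-binomial around well-separated positive/negative marker means),
TRB clonotypes drawn from a coupled bulk repertoire, and designated
"activated" clones with a fold-elevated gene module.

Everything is a pure function of (config, seed): the same config yields the
same tables, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import sparse

from clonodyn.errors import ConfigError
from clonodyn.repertoire_io import Clone, CloneKey, Repertoire

__all__ = [
    "Spike",
    "RepertoireGeneratorConfig",
    "SyntheticTruth",
    "SCGeneratorConfig",
    "generate_repertoire_series",
    "generate_single_cell",
    "MARKER_PANEL",
    "DEFAULT_SUBSET_PROPORTIONS",
]

# standard genetic code, TCAG ordering
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    b1 + b2 + b3: _AA[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
_SENSE_CODONS = sorted(c for c, a in CODON_TABLE.items() if a != "*")

TRBV_GENES = tuple(f"TRBV{i}" for i in (2, 4, 5, 6, 7, 9, 10, 11, 12, 19, 20, 27, 28, 29, 30))
TRBJ_GENES = tuple(f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3, 4, 5))


def _translate(nt: str) -> str:
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - 2, 3))


def _random_cdr3_nt(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "TGC" + "".join(_SENSE_CODONS[i] for i in body) + "TTT"


def _make_clone_identities(n: int, rng: np.random.Generator) -> list[Clone]:
    """Unique synthetic rearrangements (CDR3 length 12-16 codons)."""
    seen: set[str] = set()
    clones: list[Clone] = []
    while len(clones) < n:
        nt = _random_cdr3_nt(rng, int(rng.integers(12, 17)))
        if nt in seen:
            continue
        seen.add(nt)
        clones.append(
            Clone(
                cdr3_nt=nt,
                cdr3_aa=_translate(nt),
                v_call=str(rng.choice(TRBV_GENES)),
                j_call=str(rng.choice(TRBJ_GENES)),
                templates=0,
                productive=True,
            )
        )
    return clones


@dataclass(frozen=True)
class Spike:
    """A programmed expansion: multiply ``clone``'s frequency by ``fold`` at
    ``timepoint``. ``clone="new"`` introduces a clonotype absent at all other
    timepoints; its frequency at the spike timepoint is ``fold / N`` (a
    fold-change over the one-template detection floor)."""

    clone: int | str
    fold: float
    timepoint: str


@dataclass
class RepertoireGeneratorConfig:
    """Study conditions for a synthetic longitudinal repertoire series.

    Defaults echo survey-depth bulk immunosequencing at desk scale:
    5,000 clones under a Pareto(alpha=2) size law sampled at
    N = 20,000 templates per timepoint.
    """

    n_clones: int = 5000
    clone_frequency_law: str = "powerlaw"
    alpha: float = 2.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    n_templates: int = 20000
    phi: float = 0.0
    timepoints: tuple[str, ...] = ("Day0", "EOC2")
    spikes: tuple[Spike, ...] = ()
    pinned_frequencies: dict[int, float] = dc_field(default_factory=dict)
    subject_id: str = "SYN1"
    compartment: str = "PB"
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Generator ground truth, sufficient to score any detection run."""

    keys: list[CloneKey]
    base_frequencies: np.ndarray
    realized_frequencies: dict[str, np.ndarray]
    spiked: pd.DataFrame  # clone_index, cdr3_nt, v_gene, j_gene, fold, timepoint, baseline_frequency
    phi: float
    seed: int

    def spiked_keys(self, timepoint: str | None = None) -> list[CloneKey]:
        df = self.spiked
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return [CloneKey(*t) for t in df[["cdr3_nt", "v_gene", "j_gene"]].itertuples(index=False)]


def _base_frequencies(cfg: RepertoireGeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.clone_frequency_law == "powerlaw":
        if cfg.alpha <= 1.0:
            raise ConfigError("powerlaw alpha must exceed 1")
        u = rng.uniform(size=cfg.n_clones)
        # truncate the Pareto tail so no single clone can swamp the sample
        # (patient repertoires are dominated-but-diverse, not monoclonal)
        sizes = np.minimum(u ** (-1.0 / (cfg.alpha - 1.0)), 1e4)
    elif cfg.clone_frequency_law == "lognormal":
        sizes = rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, size=cfg.n_clones)
    else:
        raise ConfigError(f"unknown clone_frequency_law {cfg.clone_frequency_law!r}")
    f = sizes / sizes.sum()
    if cfg.pinned_frequencies:
        pinned_idx = np.array(sorted(cfg.pinned_frequencies), dtype=int)
        if pinned_idx.min() < 0 or pinned_idx.max() >= cfg.n_clones:
            raise ConfigError("pinned clone index out of range")
        pinned_f = np.array([cfg.pinned_frequencies[i] for i in pinned_idx])
        if pinned_f.sum() >= 1.0:
            raise ConfigError("pinned frequencies must sum to < 1")
        mask = np.ones(cfg.n_clones, bool)
        mask[pinned_idx] = False
        f[mask] *= (1.0 - pinned_f.sum()) / f[mask].sum()
        f[pinned_idx] = pinned_f
    return f


def _beta_perturb(f: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Draw per-clone frequencies from Beta(mean=f, a+b=(1-phi)/phi), then
    renormalize to the simplex (the one place marginals are only
    approximately beta-binomial)."""
    if phi <= 0.0:
        return f
    conc = (1.0 - phi) / phi
    pos = f > 0
    p = np.zeros_like(f)
    p[pos] = rng.beta(f[pos] * conc, (1.0 - f[pos]) * conc)
    total = p.sum()
    if total <= 0:
        return f
    return p / total


def generate_repertoire_series(
    config: RepertoireGeneratorConfig,
) -> tuple[dict[str, Repertoire], SyntheticTruth]:
    """Generate one subject's repertoires across timepoints with known truth.

    Per timepoint: base frequencies (drawn once) are spiked, renormalized,
    beta-perturbed at dispersion ``phi``, and sampled as multinomial template
    counts at ``N``; zero-count clones are simply absent from that sample.
    """
    rng = np.random.default_rng(config.seed)
    base = _base_frequencies(config, rng)

    new_spikes = [s for s in config.spikes if s.clone == "new"]
    for s in config.spikes:
        if s.clone != "new" and not (0 <= int(s.clone) < config.n_clones):
            raise ConfigError(f"spike on nonexistent clone {s.clone}")
    n_total = config.n_clones + len(new_spikes)
    identities = _make_clone_identities(n_total, rng)
    keys = [c.key for c in identities]
    base_full = np.concatenate([base, np.zeros(len(new_spikes))])

    spike_rows = []
    spike_idx: dict[int, tuple[int, float, str]] = {}
    resolved: list[tuple[int, float, str]] = []
    next_new = config.n_clones
    for s in config.spikes:
        if s.clone == "new":
            idx = next_new
            next_new += 1
        else:
            idx = int(s.clone)
        resolved.append((idx, float(s.fold), s.timepoint))
        k = keys[idx]
        spike_rows.append(
            {
                "clone_index": idx,
                "cdr3_nt": k.cdr3_nt,
                "v_gene": k.v_gene,
                "j_gene": k.j_gene,
                "fold": float(s.fold),
                "timepoint": s.timepoint,
                "baseline_frequency": float(base_full[idx]),
            }
        )

    repertoires: dict[str, Repertoire] = {}
    realized: dict[str, np.ndarray] = {}
    for tp in config.timepoints:
        f = base_full.copy()
        for idx, fold, sp_tp in resolved:
            if sp_tp != tp:
                continue
            if f[idx] > 0:
                f[idx] *= fold
            else:
                f[idx] = fold / config.n_templates
        f = f / f.sum()
        f = _beta_perturb(f, config.phi, rng)
        realized[tp] = f
        counts = rng.multinomial(config.n_templates, f)
        rep = Repertoire(
            subject_id=config.subject_id, timepoint=tp, compartment=config.compartment
        )
        for i in np.nonzero(counts)[0]:
            c = identities[i]
            rep.add(
                Clone(
                    cdr3_nt=c.cdr3_nt,
                    cdr3_aa=c.cdr3_aa,
                    v_call=c.v_call,
                    j_call=c.j_call,
                    templates=int(counts[i]),
                    productive=True,
                )
            )
        repertoires[tp] = rep

    truth = SyntheticTruth(
        keys=keys,
        base_frequencies=base_full,
        realized_frequencies=realized,
        spiked=pd.DataFrame(
            spike_rows,
            columns=[
                "clone_index", "cdr3_nt", "v_gene", "j_gene",
                "fold", "timepoint", "baseline_frequency",
            ],
        ),
        phi=config.phi,
        seed=config.seed,
    )
    return repertoires, truth


# ---------------------------------------------------------------------------
# single-cell generation
# ---------------------------------------------------------------------------

#: ADT marker panel (matches the gating requirements downstream).
MARKER_PANEL = (
    "CD3", "CD4", "CD8", "CCR7", "CD45RA", "CD45RO", "CD127", "CD25",
    "PD-1", "TIM-3", "CD27", "HLA-DR", "4-1BB",
)

#: Positive markers per subset; everything else on the panel is negative
#: (activation markers are switched on separately for activated clones).
SUBSET_POSITIVE_MARKERS: dict[str, tuple[str, ...]] = {
    "CD4_naive": ("CD3", "CD4", "CCR7", "CD45RA", "CD127", "CD27"),
    "CD4_CM": ("CD3", "CD4", "CCR7", "CD45RO", "CD127", "CD27"),
    "CD4_EM": ("CD3", "CD4", "CD45RO", "CD127"),
    "CD4_TE": ("CD3", "CD4", "CD45RA"),
    "Treg": ("CD3", "CD4", "CD25", "CD45RO"),
    "CD8_naive": ("CD3", "CD8", "CCR7", "CD45RA", "CD127", "CD27"),
    "CD8_CM": ("CD3", "CD8", "CCR7", "CD45RO", "CD127", "CD27"),
    "CD8_EM": ("CD3", "CD8", "CD45RO", "CD127"),
    "CD8_TE": ("CD3", "CD8", "CD45RA"),
}

DEFAULT_SUBSET_PROPORTIONS: dict[str, float] = {
    "CD4_naive": 0.15,
    "CD4_CM": 0.15,
    "CD4_EM": 0.12,
    "CD4_TE": 0.05,
    "Treg": 0.05,
    "CD8_naive": 0.12,
    "CD8_CM": 0.10,
    "CD8_EM": 0.16,
    "CD8_TE": 0.10,
}

ACTIVATION_MARKERS = ("PD-1", "TIM-3", "HLA-DR", "4-1BB", "CD27")


@dataclass
class SCGeneratorConfig:
    """Study conditions for one synthetic single-cell sample.

    ADT counts are negative-binomial around a positive mean of 160 and a
    negative mean of 10 (16-fold separation, the well-separated regime ADT
    staining shows for these lineage markers; NB size 12 keeps the two modes
    cleanly resolved). A small CD3-negative contaminant fraction emulates
    imperfect FACS enrichment (truth label "unassigned", no TCR). Gene
    counts are Poisson with per-gene lognormal rates and a lognormal
    per-cell size factor; designated activated clones have
    ``module_fold``-elevated rates on the genes of the module block.
    """

    n_cells: int = 3000
    subset_proportions: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_SUBSET_PROPORTIONS)
    )
    non_t_fraction: float = 0.02
    adt_positive_mean: float = 160.0
    adt_negative_mean: float = 10.0
    adt_nb_size: float = 12.0
    n_genes: int = 2000
    module_start: int = 100
    module_size: int = 20
    module_fold: float = 4.0
    activated_clone_indices: tuple[int, ...] = ()
    activated_subset: str = "CD8_EM"
    trb_recovery: float = 0.9
    seed: int = 0


def _nb_counts(mean, size, shape, rng) -> np.ndarray:
    # negative binomial via gamma-Poisson mixture (vectorized over means)
    lam = rng.gamma(size, np.asarray(mean) / size, size=shape)
    return rng.poisson(lam)


def generate_single_cell(
    config: SCGeneratorConfig, bulk: Repertoire | None = None
):
    """Generate a single-cell table with subset / clonotype / module truth.

    Returns ``(cells, truth)`` where ``cells`` is a
    :class:`~clonodyn.sc_link.SingleCellTable` and ``truth`` a per-cell
    DataFrame with the generating subset label, clonotype, and activation
    flag. TRB clonotypes are drawn from the coupled bulk repertoire's
    productive frequencies when ``bulk`` is given, else from a small
    synthetic clone pool.
    """
    from clonodyn.sc_link import SingleCellTable  # deferred: avoid import cycle

    rng = np.random.default_rng(config.seed)
    props = config.subset_proportions
    unknown = set(props) - set(SUBSET_POSITIVE_MARKERS)
    if unknown:
        raise ConfigError(f"unknown subsets in proportions: {sorted(unknown)}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"subset proportions must sum to 1, got {total}")
    labels = sorted(props)
    p = np.array([props[s] for s in labels])
    subset_idx = rng.choice(len(labels), size=config.n_cells, p=p)
    subsets = np.array(labels, dtype=object)[subset_idx]
    non_t = rng.uniform(size=config.n_cells) < config.non_t_fraction
    subsets[non_t] = "unassigned"

    # clonotype assignment
    if bulk is not None:
        counts = bulk.productive_counts()
        pool_keys = sorted(counts)
        pool_f = np.array([counts[k] for k in pool_keys], dtype=float)
        pool_f /= pool_f.sum()
        pool_aa = {
            k: bulk.clones[k].cdr3_aa for k in pool_keys
        }
    else:
        pool_clones = _make_clone_identities(200, rng)
        pool_keys = [c.key for c in pool_clones]
        pool_f = np.full(len(pool_keys), 1.0 / len(pool_keys))
        pool_aa = {c.key: c.cdr3_aa for c in pool_clones}
    draw = rng.choice(len(pool_keys), size=config.n_cells, p=pool_f)
    recovered = (rng.uniform(size=config.n_cells) < config.trb_recovery) & ~non_t
    trb_nt = np.array(
        [pool_keys[i].cdr3_nt if r else "" for i, r in zip(draw, recovered)], dtype=object
    )
    trb_aa = np.array(
        [pool_aa[pool_keys[i]] if r else "" for i, r in zip(draw, recovered)], dtype=object
    )
    trb_v = np.array(
        [pool_keys[i].v_gene if r else "" for i, r in zip(draw, recovered)], dtype=object
    )
    trb_j = np.array(
        [pool_keys[i].j_gene if r else "" for i, r in zip(draw, recovered)], dtype=object
    )

    activated_keys = set()
    if config.activated_clone_indices:
        for i in config.activated_clone_indices:
            if not (0 <= i < len(pool_keys)):
                raise ConfigError(f"activated clone index {i} out of range")
            activated_keys.add(pool_keys[i])
    activated = np.array(
        [r and pool_keys[i] in activated_keys for i, r in zip(draw, recovered)], dtype=bool
    )
    if config.activated_subset:
        # activated clones are phenotypically coherent: force their cells'
        # subset to the configured one
        subsets = subsets.copy()
        subsets[activated] = config.activated_subset

    # ADT counts
    adt_means = np.full((config.n_cells, len(MARKER_PANEL)), config.adt_negative_mean)
    marker_col = {m: j for j, m in enumerate(MARKER_PANEL)}
    for s, positives in SUBSET_POSITIVE_MARKERS.items():
        rows = subsets == s
        for m in positives:
            adt_means[rows, marker_col[m]] = config.adt_positive_mean
    for m in ACTIVATION_MARKERS:
        adt_means[activated, marker_col[m]] = config.adt_positive_mean
    adt = _nb_counts(adt_means, config.adt_nb_size, adt_means.shape, rng)

    # gene expression
    gene_rates = rng.lognormal(-1.0, 1.0, size=config.n_genes)
    cell_factor = rng.lognormal(0.0, 0.3, size=config.n_cells)
    module_size = min(config.module_size, config.n_genes)
    module_start = min(config.module_start, config.n_genes - module_size)
    module = np.arange(module_start, module_start + module_size)
    # the activation module consists of expressed genes (a fold change on a
    # gene with no baseline expression is not an activation signal)
    gene_rates[module] = rng.lognormal(0.0, 0.5, size=module_size)
    rates = np.outer(cell_factor, gene_rates)
    rates[np.ix_(activated, module)] *= config.module_fold
    gex = rng.poisson(rates)
    genes = [f"GENE{g:04d}" for g in range(config.n_genes)]

    barcodes = [f"CELL{i:05d}-1" for i in range(config.n_cells)]
    obs = pd.DataFrame(
        {
            "trb_cdr3_nt": trb_nt,
            "trb_cdr3_aa": trb_aa,
            "trb_v_gene": trb_v,
            "trb_j_gene": trb_j,
            "tra_cdr3_aa": ["" for _ in range(config.n_cells)],
            "subset": ["unassigned"] * config.n_cells,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adt_df = pd.DataFrame(adt, index=obs.index, columns=list(MARKER_PANEL))
    cells = SingleCellTable(
        obs=obs, adt=adt_df, gene_counts=sparse.csr_matrix(gex), genes=genes
    )
    truth = pd.DataFrame(
        {
            "subset": subsets,
            "trb_cdr3_nt": [pool_keys[i].cdr3_nt for i in draw],
            "activated": activated,
        },
        index=obs.index,
    )
    truth.attrs["module_genes"] = [genes[g] for g in module]
    return cells, truth
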