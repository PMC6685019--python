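"""Cohort-style targeted-sequencing mutation tables.

Handles mutation-call tables in the style of gridded normal-oesophagus
sequencing studies: the epithelium is cut into a contiguous grid of ~2 mm²
samples, each deep-sequenced against a gene panel.  The module applies the
analysis filters (autosomes only; LOH assumed for protein-altering NOTCH1
mutations, heterozygosity elsewhere; a neutral-proxy subset of synonymous
mutations and mutations in non-expressed genes), converts VAFs to clone
areas, merges clones that span grid-adjacent samples, and can generate
synthetic cohort fixtures with planted neutral and selected clones for
end-to-end exercises of the pipeline.

Expected table header (TSV/CSV)::

    donor sample_id grid_row grid_col gene chrom pos ref alt effect vaf depth
    sample_area_mm2 [aachange]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "donor", "sample_id", "grid_row", "grid_col", "gene", "chrom", "pos",
    "ref", "alt", "effect", "vaf", "depth", "sample_area_mm2",
]
EFFECT_CLASSES = {"synonymous", "missense", "nonsense", "splice", "other"}
MUTATION_KEY = ["chrom", "pos", "ref", "alt"]

#: Default per-sample epithelial area, mm².
DEFAULT_SAMPLE_AREA = 2.0

#: Synonymous variant excluded from the neutral proxy (affects splicing).
SPLICE_AFFECTING_SYNONYMOUS = ("TP53", "T125T")


def load_expression_table(path=None) -> pd.Series:
    """Gene → TPM mapping.  Without ``path``, loads the packaged oesophagus
    table (positively selected panel genes plus the panel's 0.0-TPM genes)."""
    if path is None:
        src = resources.files("epiclone").joinpath("data/expression_oesophagus.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    if not {"gene", "tpm"} <= set(df.columns):
        raise ValueError("expression table needs 'gene' and 'tpm' columns")
    if (df["tpm"] < 0).any():
        raise ValueError("TPM values must be non-negative")
    return df.set_index("gene")["tpm"]


def nonexpressed_genes(expression: pd.Series | None = None) -> set[str]:
    """Panel genes at the conservative non-expression threshold of 0.0 TPM."""
    expression = load_expression_table() if expression is None else expression
    return set(expression.index[expression == 0.0])


def read_mutation_table(path_or_buffer, sep=None) -> pd.DataFrame:
    """Read and validate a cohort mutation-call table.

    Missing required columns raise; individual rows failing validation
    (VAF outside (0, 1], unknown effect class) are dropped with a logged
    reason.  Unknown effect classes are first coerced to ``other``.
    """
    df = pd.read_csv(path_or_buffer, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing required columns: {missing}")
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)  # "17" and 17 are the same label
    bad_effect = ~df["effect"].isin(EFFECT_CLASSES)
    if bad_effect.any():
        logger.warning(
            "%d rows with unknown effect class mapped to 'other'", int(bad_effect.sum())
        )
        df.loc[bad_effect, "effect"] = "other"
    bad_vaf = ~((df["vaf"] > 0) & (df["vaf"] <= 1))
    if bad_vaf.any():
        logger.warning("rejecting %d rows with VAF outside (0, 1]", int(bad_vaf.sum()))
        df = df[~bad_vaf]
    return df.reset_index(drop=True)


def write_mutation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def autosome_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep calls on chromosomes 1–22 (sex chromosomes have ambiguous copy
    number, so VAF→area scaling is only defined on autosomes)."""
    chrom = calls["chrom"].astype(str).str.removeprefix("chr")
    keep = chrom.isin({str(i) for i in range(1, 23)})
    dropped = int((~keep).sum())
    if dropped:
        logger.info("autosome filter removed %d rows", dropped)
    return calls[keep.to_numpy(dtype=bool)].reset_index(drop=True)


def assign_zygosity(gene: str, effect: str) -> str:
    """LOH for protein-altering NOTCH1 mutations (loss of heterozygosity
    frequently co-occurs with them, and assuming it gives conservative,
    smaller clone sizes); heterozygous otherwise."""
    if gene == "NOTCH1" and effect != "synonymous":
        return "loh"
    return "heterozygous"


def clone_area(vaf: float, sample_area: float, zygosity: str) -> float:
    """Clone area implied by a VAF within one sample: 2·vaf·area for
    heterozygous clones, vaf·area under LOH, capped at the sample area."""
    scale = 2.0 if zygosity == "heterozygous" else 1.0
    return float(min(scale * vaf * sample_area, sample_area))


def per_sample_clone_areas(calls: pd.DataFrame) -> pd.DataFrame:
    """Spaced-design readout: one clone per (sample, mutation) row, area from
    that sample alone."""
    out = calls.copy()
    out["zygosity"] = [
        assign_zygosity(g, e) for g, e in zip(out["gene"], out["effect"])
    ]
    out["area_mm2"] = [
        clone_area(v, a, z)
        for v, a, z in zip(out["vaf"], out["sample_area_mm2"], out["zygosity"])
    ]
    return out


def merge_gridded(calls: pd.DataFrame, adjacency: str = "rook") -> pd.DataFrame:
    """Merge identical mutations found in grid-adjacent samples of a donor.

    Rows sharing (donor, chrom, pos, ref, alt) whose samples form a
    connected patch under grid adjacency (edge/rook by default) become one
    clone whose area is the sum of the per-sample clone areas.  Returns one
    row per merged clone with ``member_samples`` and ``n_samples``.
    """
    if adjacency not in ("rook", "queen"):
        raise ValueError("adjacency must be 'rook' or 'queen'")
    if calls[["donor", "sample_id", *MUTATION_KEY]].duplicated().any():
        raise ValueError("duplicate (sample, mutation) rows")
    calls = per_sample_clone_areas(calls)
    records = []
    for (donor, *key), grp in calls.groupby(["donor", *MUTATION_KEY], sort=False):
        g = nx.Graph()
        coords = {}
        for _, row in grp.iterrows():
            coords[row["sample_id"]] = (int(row["grid_row"]), int(row["grid_col"]))
            g.add_node(row["sample_id"])
        for a in g.nodes:
            for b in g.nodes:
                if a < b and _adjacent(coords[a], coords[b], adjacency):
                    g.add_edge(a, b)
        by_sample = grp.set_index("sample_id")
        for comp in nx.connected_components(g):
            members = sorted(comp)
            sub = by_sample.loc[members]
            records.append(
                {
                    "donor": donor,
                    **dict(zip(MUTATION_KEY, key)),
                    "gene": sub["gene"].iloc[0],
                    "effect": sub["effect"].iloc[0],
                    "zygosity": sub["zygosity"].iloc[0],
                    "member_samples": ",".join(str(s) for s in members),
                    "n_samples": len(members),
                    "area_mm2": float(sub["area_mm2"].sum()),
                }
            )
    return pd.DataFrame.from_records(records)


def _adjacent(a: tuple[int, int], b: tuple[int, int], adjacency: str) -> bool:
    dr, dc = abs(a[0] - b[0]), abs(a[1] - b[1])
    if adjacency == "rook":
        return dr + dc == 1
    return max(dr, dc) == 1 and (dr or dc)


def neutral_proxy_subset(
    calls: pd.DataFrame, expression: pd.Series | None = None
) -> pd.DataFrame:
    """Mutations not identifiable as under selection: synonymous calls plus
    any call in a non-expressed (0.0 TPM) gene.

    The splice-affecting synonymous TP53 variant T125T is excluded when an
    ``aachange`` column is present.  Genes absent from the expression table
    are treated as expressed (logged).  Idempotent and order-independent.
    """
    expression = load_expression_table() if expression is None else expression
    unknown = sorted(set(calls["gene"]) - set(expression.index))
    if unknown:
        logger.warning("genes missing from expression table treated as expressed: %s",
                       ", ".join(unknown))
    silent_genes = nonexpressed_genes(expression)
    keep = (calls["effect"] == "synonymous") | calls["gene"].isin(silent_genes)
    if "aachange" in calls.columns:
        gene, aa = SPLICE_AFFECTING_SYNONYMOUS
        keep &= ~((calls["gene"] == gene) & (calls["aachange"] == aa))
    return calls[keep].reset_index(drop=True)


def gene_level_comparison(
    calls: pd.DataFrame, genes: list[str], effect: str = "nonsense"
) -> pd.DataFrame:
    """Per-gene median VAF of ``effect`` mutations versus all synonymous
    mutations, with a one-sided rank-sum p (gene clones larger).

    Donors are pooled.  Genes with no qualifying calls are reported with
    missing statistics.
    """
    from .stats import rank_sum_one_sided

    syn = calls.loc[calls["effect"] == "synonymous", "vaf"].to_numpy()
    if syn.size == 0:
        raise ValueError("no synonymous reference mutations in table")
    rows = []
    for gene in genes:
        v = calls.loc[(calls["gene"] == gene) & (calls["effect"] == effect), "vaf"]
        v = v.to_numpy()
        rows.append(
            {
                "gene": gene,
                "n_calls": int(v.size),
                "median_vaf": float(np.median(v)) if v.size else np.nan,
                "p_greater_than_synonymous": (
                    rank_sum_one_sided(v, syn) if v.size else np.nan
                ),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["synonymous_median_vaf"] = float(np.median(syn))
    out.attrs["n_synonymous"] = int(syn.size)
    return out


# ---------------------------------------------------------------------------
# synthetic cohort fixtures


@dataclass(frozen=True)
class CohortFixtureConfig:
    """Synthetic gridded-cohort generator settings.

    Plants a mixture of small neutral clones and larger clones in selected
    genes as connected patches on the sample grid, then pushes the implied
    per-sample cell fractions through the binomial sequencing model, so the
    emitted table has the statistical structure the analyses assume.
    """

    n_donors: int = 1
    grid_rows: int = 10
    grid_cols: int = 10
    sample_area_mm2: float = DEFAULT_SAMPLE_AREA
    cells_per_mm2: float = 5000.0  # progenitors per mm² of epithelium
    panel_genes: tuple[str, ...] = (
        "TP53", "NOTCH1", "NOTCH2", "NOTCH3", "FAT1", "ADAM29", "GRM3", "SPHKAP",
    )
    selected_genes: tuple[str, ...] = ("TP53", "NOTCH1", "NOTCH2", "NOTCH3", "FAT1")
    n_neutral_clones: int = 400
    n_selected_clones: int = 20
    neutral_mean_area: float = 0.15  # mm², exponential
    # selected clone areas are lognormal (median selected_median_area,
    # log-sd selected_sigma), giving the heavy tail of driver-mutant clones
    selected_median_area: float = 4.0  # mm²
    selected_sigma: float = 0.7
    # a clone occupies each of its samples only partially; the fill fraction
    # is drawn uniformly from this range, so large clones spread over many
    # samples with sub-cap per-sample VAFs
    fill_fraction_range: tuple[float, float] = (0.3, 0.7)
    max_span_samples: int = 16
    depth: int = 1000
    min_reads: int = 10


def generate_cohort_fixture(
    config: CohortFixtureConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Emit a synthetic cohort mutation table (see CohortFixtureConfig).

    Selected-gene clones are placed as rook-connected patches spanning
    several samples; neutral clones sit inside a single sample.  Per-sample
    VAFs follow from clone area (heterozygous scaling) with binomial read
    noise at constant depth; sub-threshold observations are dropped, like
    the real detection limit.
    """
    chroms = {g: str(1 + i % 22) for i, g in enumerate(config.panel_genes)}
    rows = []
    mut_counter = 0
    for donor_i in range(config.n_donors):
        donor = f"D{donor_i:02d}"
        for kind, n_clones in (
            ("neutral", config.n_neutral_clones),
            ("selected", config.n_selected_clones),
        ):
            for _ in range(n_clones):
                if kind == "selected":
                    gene = config.selected_genes[
                        rng.integers(len(config.selected_genes))
                    ]
                    effect = ["missense", "nonsense", "splice"][rng.integers(3)]
                    area = rng.lognormal(
                        np.log(config.selected_median_area), config.selected_sigma
                    )
                else:
                    gene = config.panel_genes[rng.integers(len(config.panel_genes))]
                    effect = "synonymous" if rng.random() < 0.6 else "missense"
                    area = rng.exponential(config.neutral_mean_area)
                area = max(area, 0.005)
                fill = rng.uniform(*config.fill_fraction_range)
                n_samples = int(np.ceil(area / (fill * config.sample_area_mm2)))
                patch = _random_patch(
                    config.grid_rows, config.grid_cols,
                    min(max(n_samples, 1), config.max_span_samples),
                    rng,
                )
                # cap total area at what the patch can physically hold
                area = min(area, 0.95 * len(patch) * config.sample_area_mm2)
                mut_counter += 1
                pos = 10_000 + mut_counter
                per_sample = _split_area(area, patch, config.sample_area_mm2, rng)
                for (r, c), a in zip(patch, per_sample):
                    f = a / config.sample_area_mm2  # cell fraction in sample
                    vaf_true = 0.5 * f
                    reads = rng.binomial(config.depth, min(vaf_true, 1.0))
                    if reads < config.min_reads:
                        continue
                    rows.append(
                        {
                            "donor": donor,
                            "sample_id": f"{donor}_r{r}c{c}",
                            "grid_row": r,
                            "grid_col": c,
                            "gene": gene,
                            "chrom": chroms[gene],
                            "pos": pos,
                            "ref": "C",
                            "alt": "T",
                            "effect": effect,
                            "vaf": reads / config.depth,
                            "depth": config.depth,
                            "sample_area_mm2": config.sample_area_mm2,
                            "true_area_mm2": a,
                            "clone_kind": kind,
                        }
                    )
    return pd.DataFrame(rows)


def _random_patch(rows: int, cols: int, size: int, rng) -> list[tuple[int, int]]:
    """Random rook-connected patch of grid samples."""
    start = (int(rng.integers(rows)), int(rng.integers(cols)))
    patch = [start]
    frontier = {start}
    while len(patch) < size:
        r, c = patch[int(rng.integers(len(patch)))]
        options = [
            (r + dr, c + dc)
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0))
            if 0 <= r + dr < rows and 0 <= c + dc < cols
            and (r + dr, c + dc) not in frontier
        ]
        if not options:
            break
        nxt = options[int(rng.integers(len(options)))]
        patch.append(nxt)
        frontier.add(nxt)
    return patch


def _split_area(area: float, patch, sample_area: float, rng) -> np.ndarray:
    """Partition a clone's area over its patch, capped per sample."""
    k = len(patch)
    weights = rng.dirichlet(np.ones(k)) if k > 1 else np.ones(1)
    per = area * weights
    # redistribute overflow above the per-sample cap, greedily
    for _ in range(k):
        over = per - sample_area
        excess = over[over > 0].sum()
        if excess <= 0:
            break
        per = np.minimum(per, sample_area)
        room = per < sample_area
        if not room.any():
            break
        per[room] += excess / room.sum()
    return np.minimum(per, sample_area)
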