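"""Synthetic droplet scRNA-seq samples with planted QC populations.

The generator plants cell populations that reproduce the metric structure
automated QC relies on, with known truth labels:

* ``good`` — healthy cells: high totals, low mitochondrial fraction;
* ``debris`` — broken cells / empty-ish droplets: low totals, shifted
  spliced fraction;
* ``high_mito`` — dying cells: good-like totals, ~40% mitochondrial counts;
* ``soup_heavy`` — droplets dominated by ambient RNA (high soup fraction);
* ``doublet`` — element-wise sums of two sampled good cells, carrying high
  doublet scores.

Per cell, a total UMI count is drawn from the population's log-normal, the
mitochondrial mass of a shared power-law expression profile is rescaled to
the cell's drawn mitochondrial fraction, and gene counts are drawn
multinomially conditional on the total — so totals and mito fractions are
exactly controllable, which keeps the planted truth simple.  Spliced totals,
soup fractions and doublet scores come from per-population Beta
distributions.  Everything is driven by one seed; regeneration is
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError
from .qc_metrics import AuxiliaryCellData, CountsMatrix


@dataclass
class PopulationSpec:
    """One planted population: size plus its metric-generating distributions.

    ``total_counts`` is (meanlog, sdlog) of a log-normal; the remaining
    entries are (a, b) of Beta distributions for the mitochondrial fraction,
    ambient (soup) fraction, spliced fraction and doublet score.
    """

    name: str
    n_cells: int
    total_counts: tuple[float, float] = (8.5, 0.4)
    mito_frac: tuple[float, float] = (2.0, 38.0)
    soup_frac: tuple[float, float] = (1.0, 19.0)
    spliced_frac: tuple[float, float] = (30.0, 10.0)
    doublet_score: tuple[float, float] = (2.0, 18.0)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigError(f"population {self.name}: n_cells < 0")
        for attr in ("total_counts", "mito_frac", "soup_frac", "spliced_frac", "doublet_score"):
            pair = getattr(self, attr)
            if len(pair) != 2 or (attr != "total_counts" and min(pair) <= 0):
                raise ConfigError(f"population {self.name}: bad {attr} parameters")


def default_populations(
    n_good: int = 1500,
    n_debris: int = 300,
    n_high_mito: int = 200,
    n_soup_heavy: int = 100,
    n_doublet: int = 100,
) -> list[PopulationSpec]:
    """The standard five-population sample used throughout the test-bench.

    Good cells centre at ~5,000 counts and 5% mitochondrial; debris at ~150
    counts; dying cells at ~40% mitochondrial; soup-heavy droplets carry a
    ~40% ambient fraction but are otherwise healthy; doublets are pair-sums
    of good cells with high doublet scores.
    """
    return [
        PopulationSpec("good", n_good, (8.5, 0.4), (2, 38), (1, 19), (30, 10), (2, 18)),
        PopulationSpec("debris", n_debris, (5.0, 0.5), (4, 16), (1, 19), (12, 12), (2, 18)),
        PopulationSpec("high_mito", n_high_mito, (7.8, 0.4), (16, 24), (1, 19), (30, 10), (2, 18)),
        PopulationSpec("soup_heavy", n_soup_heavy, (8.5, 0.4), (2, 38), (8, 12), (30, 10), (2, 18)),
        PopulationSpec("doublet", n_doublet, (8.5, 0.4), (2, 38), (1, 19), (30, 10), (20, 5)),
    ]


@dataclass
class SyntheticSample:
    """Generated counts, auxiliary vectors and per-cell truth labels."""

    counts: CountsMatrix
    aux: AuxiliaryCellData
    truth: np.ndarray
    params: dict = field(default_factory=dict)


def _gene_names(n_genes: int, n_mito: int, n_ribo: int, n_hb: int) -> list[str]:
    if n_mito + n_ribo + n_hb >= n_genes:
        raise ConfigError("special gene sets exceed total gene count")
    names = [f"MT-SYN{i + 1}" for i in range(n_mito)]
    names += [f"RPS-SYN{i + 1}" for i in range(n_ribo)]
    names += [f"HBB-SYN{i + 1}" for i in range(n_hb)]
    names += [f"GENE{i + 1:05d}" for i in range(n_genes - len(names))]
    return names


def generate_sample(
    specs: list[PopulationSpec] | None = None,
    n_genes: int = 2000,
    n_mito_genes: int = 13,
    n_ribo_genes: int = 40,
    n_hb_genes: int = 5,
    seed: int = 0,
) -> SyntheticSample:
    """Generate one synthetic sample with planted populations.

    Gene baseline expression follows a power-law (Zipf-like) profile over a
    seeded gene permutation.  Doublet count vectors are sums of two good
    cells drawn with replacement, so a non-empty doublet population requires
    a non-empty good population.
    """
    specs = specs if specs is not None else default_populations()
    total_cells = sum(s.n_cells for s in specs)
    if total_cells < 100:
        raise ConfigError(f"total cells {total_cells} < 100")
    rng = np.random.default_rng(seed)

    gene_ids = _gene_names(n_genes, n_mito_genes, n_ribo_genes, n_hb_genes)
    mito = np.zeros(n_genes, dtype=bool)
    mito[:n_mito_genes] = True

    # Power-law profile assigned to a random gene order, normalized within
    # the mito and non-mito blocks separately (per-cell mito mass is planted).
    ranks = rng.permutation(n_genes)
    base = 1.0 / (ranks + 1.0)
    p_mito = base * mito
    p_rest = base * ~mito
    p_mito /= p_mito.sum()
    p_rest /= p_rest.sum()

    by_pop: dict[str, PopulationSpec] = {s.name: s for s in specs}
    doublet_spec = by_pop.get("doublet")
    if doublet_spec is not None and doublet_spec.n_cells and (
        "good" not in by_pop or by_pop["good"].n_cells == 0
    ):
        raise ConfigError("doublet population requires good cells to sum")

    rows: list[np.ndarray] = []
    truth: list[str] = []
    soup: list[float] = []
    spliced_frac: list[float] = []
    dscore: list[float] = []

    def draw_cell(spec: PopulationSpec) -> np.ndarray:
        total = max(1, int(round(rng.lognormal(*spec.total_counts))))
        f = rng.beta(*spec.mito_frac)
        p = f * p_mito + (1.0 - f) * p_rest
        return rng.multinomial(total, p)

    good_rows: list[np.ndarray] = []
    for spec in specs:
        if spec.name == "doublet":
            continue
        for _ in range(spec.n_cells):
            vec = draw_cell(spec)
            rows.append(vec)
            if spec.name == "good":
                good_rows.append(vec)
            truth.append(spec.name)
            soup.append(rng.beta(*spec.soup_frac))
            spliced_frac.append(rng.beta(*spec.spliced_frac))
            dscore.append(rng.beta(*spec.doublet_score))

    if doublet_spec is not None:
        for _ in range(doublet_spec.n_cells):
            i, j = rng.integers(len(good_rows)), rng.integers(len(good_rows))
            rows.append(good_rows[i] + good_rows[j])
            truth.append("doublet")
            soup.append(rng.beta(*doublet_spec.soup_frac))
            spliced_frac.append(rng.beta(*doublet_spec.spliced_frac))
            dscore.append(rng.beta(*doublet_spec.doublet_score))

    counts = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    totals = np.asarray(counts.sum(axis=1)).ravel()
    spliced_total = rng.binomial(totals, np.asarray(spliced_frac)).astype(float)

    cell_ids = [f"CELL{i + 1:06d}" for i in range(counts.shape[0])]
    aux = AuxiliaryCellData(
        spliced_total=spliced_total,
        unspliced_total=totals - spliced_total,
        soup_fraction=np.asarray(soup),
        doublet_score=np.asarray(dscore),
    )
    params = {
        "seed": int(seed),
        "n_genes": n_genes,
        "n_mito_genes": n_mito_genes,
        "n_ribo_genes": n_ribo_genes,
        "n_hb_genes": n_hb_genes,
        "populations": [
            {
                "name": s.name,
                "n_cells": s.n_cells,
                "total_counts": list(s.total_counts),
                "mito_frac": list(s.mito_frac),
                "soup_frac": list(s.soup_frac),
                "spliced_frac": list(s.spliced_frac),
                "doublet_score": list(s.doublet_score),
            }
            for s in specs
        ],
    }
    return SyntheticSample(
        counts=CountsMatrix(cell_ids, gene_ids, counts),
        aux=aux,
        truth=np.asarray(truth),
        params=params,
    )


def write_fixture(sample: SyntheticSample, outdir: str | Path) -> dict[str, Path]:
    """Write a sample as a 10x-style triplet plus auxiliary and truth CSVs.

    Produces ``matrix.mtx`` (features x barcodes, 1-based triplets),
    ``barcodes.tsv``, ``features.tsv``, ``soup.csv``, ``doublets.csv``,
    ``spliced.csv`` and ``truth.csv``.  Reading the directory back with
    :func:`autoqc.io.read_counts` reproduces the counts exactly.
    """
    from . import io as _io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
        "soup": outdir / "soup.csv",
        "doublets": outdir / "doublets.csv",
        "spliced": outdir / "spliced.csv",
        "truth": outdir / "truth.csv",
    }
    _io.write_mtx_triplet(sample.counts, paths["matrix"].parent)

    cells = sample.counts.cell_ids
    aux = sample.aux
    with open(paths["soup"], "w") as fh:
        fh.write("barcode,soup_fraction\n")
        for bc, v in zip(cells, aux.soup_fraction):
            fh.write(f"{bc},{v:.10g}\n")
    with open(paths["doublets"], "w") as fh:
        fh.write("barcode,doublet_score\n")
        for bc, v in zip(cells, aux.doublet_score):
            fh.write(f"{bc},{v:.10g}\n")
    with open(paths["spliced"], "w") as fh:
        fh.write("barcode,spliced_total,unspliced_total\n")
        for bc, s, u in zip(cells, aux.spliced_total, aux.unspliced_total):
            fh.write(f"{bc},{s:.10g},{u:.10g}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("barcode,population\n")
        for bc, t in zip(cells, sample.truth):
            fh.write(f"{bc},{t}\n")
    return paths
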