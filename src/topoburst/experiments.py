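"""Scripted computational experiments on the supercoiling bursting model.

Each function builds the relevant network from the standard rate set
(gamma=50, b_o=2, d=1, K1=10, K2=35, R=1000, max_rcoil=4 unless overridden),
samples stationary cells with per-replicate seed streams, and returns a small
report object whose numbers are fully determined by (configuration, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import (
    correlation_matrix,
    empirical_pmf,
    fano,
    gamma_fit,
    GammaFit,
    poisson_pmf_fit,
    pzs_pmf,
)
from .kinetics import (
    DomainSpec,
    GeneSpec,
    GlobalRates,
    SystemSpec,
    build_network,
    sample_cells,
    single_gene_system,
)

__all__ = [
    "STRONG_PROMOTER_AO",
    "WEAK_PROMOTER_AO",
    "LINKED_DOMAIN_AO",
    "run_mrna_distribution_experiment",
    "run_fano_scan",
    "run_gamma_fit_experiment",
    "run_gamma_error_scan",
    "run_linked_domain_experiment",
    "run_negative_regulation_experiment",
]

STRONG_PROMOTER_AO = 100.0
WEAK_PROMOTER_AO = 20.0
#: Promoter strengths of the ten-gene, two-domain system (genes 1-5 and 6-10).
LINKED_DOMAIN_AO = (34.0, 20.0, 14.0, 10.0, 6.0, 2.0, 3.0, 2.4, 0.4, 1.0)
#: Promoter strengths of the five-gene negative-regulation domain (strong to weak).
NEGATIVE_REGULATION_AO = (34.0, 20.0, 14.0, 10.0, 6.0)

DEFAULT_BURN_IN = 10.0


def _sub_seed(seed: int, *stream: int) -> int:
    """Stable derived seed for a named sub-experiment."""
    return int(np.random.SeedSequence([int(seed), *stream]).generate_state(1, dtype=np.uint32)[0])


@dataclass
class MrnaDistributionReport:
    """Empirical mRNA pmf of one gene with Poisson and zero-spike overlays."""

    a_o: float
    supercoiling: bool
    n_cells: int
    seed: int
    fano_factor: float
    poisson_lambda: float
    on_fraction: float
    table: pd.DataFrame = field(repr=False)  # count, empirical, poisson, pzs

    def save(self, out_dir) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "mrna_pmf.tsv", sep="\t", index=False)
        meta = {k: getattr(self, k) for k in
                ("a_o", "supercoiling", "n_cells", "seed", "fano_factor",
                 "poisson_lambda", "on_fraction")}
        (out_dir / "report.json").write_text(json.dumps(meta, indent=2))


def run_mrna_distribution_experiment(
    promoter: str = "strong",
    n_cells: int = 4000,
    seed: int = 0,
    supercoiling: bool = True,
    a_o: float | None = None,
    max_rcoil: int = 4,
    K1: float = 10.0,
    K2: float = 35.0,
    R: float = 1000.0,
    gamma: float = 50.0,
    burn_in: float = DEFAULT_BURN_IN,
) -> MrnaDistributionReport:
    """Stationary mRNA distribution of a single gene (strong or weak promoter)
    with Poisson-fit and zero-spike reference curves."""
    if a_o is None:
        a_o = {"strong": STRONG_PROMOTER_AO, "weak": WEAK_PROMOTER_AO}[promoter]
    spec = single_gene_system(
        a_o=a_o, translated=False, max_rcoil=max_rcoil, K1=K1, K2=K2, R=R, gamma=gamma
    )
    net = build_network(spec, supercoiling=supercoiling)
    sample = sample_cells(net, n_cells, seed=seed, burn_in=burn_in)
    mrna = sample.gene_counts("gene1", "mrna")
    emp = empirical_pmf(mrna)
    lam_fit, pois = poisson_pmf_fit(mrna)
    lam_on = a_o * max_rcoil / gamma
    pzs = pzs_pmf(K1, K2, lam_on, n_max=len(emp) - 1)
    table = pd.DataFrame(
        {"count": np.arange(len(emp)), "empirical": emp, "poisson": pois, "pzs": pzs}
    )
    return MrnaDistributionReport(
        a_o=a_o, supercoiling=supercoiling, n_cells=n_cells, seed=seed,
        fano_factor=fano(mrna), poisson_lambda=lam_fit,
        on_fraction=K1 / (K1 + K2), table=table,
    )


def run_fano_scan(
    a_o_values: Sequence[float] | None = None,
    k1_values: Sequence[float] | None = None,
    n_cells: int = 2000,
    seed: int = 0,
    K2: float = 35.0,
    max_rcoil: int = 4,
    gamma: float = 50.0,
    R: float = 1000.0,
    burn_in: float = DEFAULT_BURN_IN,
) -> pd.DataFrame:
    """mRNA Fano factor of a single gene over an (a_o, K1) grid.

    Returns a DataFrame indexed by K1 with one column per a_o.  Genes are
    untranslated here: the Fano factor concerns the mRNA marginal only.
    """
    if a_o_values is None:
        a_o_values = np.linspace(10.0, 200.0, 8)
    if k1_values is None:
        k1_values = np.geomspace(1.0, 100.0, 8)
    out = np.empty((len(k1_values), len(a_o_values)))
    for i, k1 in enumerate(k1_values):
        for j, a_o in enumerate(a_o_values):
            spec = single_gene_system(
                a_o=a_o, translated=False, max_rcoil=max_rcoil,
                K1=k1, K2=K2, R=R, gamma=gamma,
            )
            net = build_network(spec)
            s = sample_cells(net, n_cells, seed=_sub_seed(seed, i, j), burn_in=burn_in)
            out[i, j] = fano(s.gene_counts("gene1", "mrna"))
    return pd.DataFrame(out, index=pd.Index(k1_values, name="K1"),
                        columns=pd.Index(a_o_values, name="a_o"))


@dataclass
class GammaFitReport:
    """Gamma fit of a stationary protein distribution vs the burst-model mapping."""

    fit: GammaFit
    true_shape: float          #: burst-model value a_o * max_rcoil / d
    true_scale: float          #: burst-model value b_o
    n_cells: int
    seed: int

    @property
    def pct_error_shape(self) -> float:
        return 100.0 * (self.fit.shape - self.true_shape) / self.true_shape

    @property
    def pct_error_scale(self) -> float:
        return 100.0 * (self.fit.scale - self.true_scale) / self.true_scale

    def to_dict(self) -> dict:
        return {
            "fit": self.fit.to_dict(),
            "true_shape": self.true_shape, "true_scale": self.true_scale,
            "pct_error_shape": self.pct_error_shape,
            "pct_error_scale": self.pct_error_scale,
            "n_cells": self.n_cells, "seed": self.seed,
        }

    def save(self, out_dir) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "gamma_fit.json").write_text(json.dumps(self.to_dict(), indent=2))


def run_gamma_fit_experiment(
    a_o: float = 90.0,
    b_o: float = 2.0,
    max_rcoil: int = 4,
    K1: float = 10.0,
    K2: float = 35.0,
    R: float = 1000.0,
    gamma: float = 50.0,
    d: float = 1.0,
    n_cells: int = 4000,
    seed: int = 0,
    burn_in: float = DEFAULT_BURN_IN,
) -> GammaFitReport:
    """Fit a gamma distribution to the full model's stationary protein counts
    and compare (shape, scale) against the burst-model truths
    (a_o*max_rcoil/d, b_o)."""
    spec = single_gene_system(
        a_o=a_o, b_o=b_o, max_rcoil=max_rcoil, K1=K1, K2=K2, R=R, gamma=gamma, d=d
    )
    net = build_network(spec)
    sample = sample_cells(net, n_cells, seed=seed, burn_in=burn_in)
    protein = sample.gene_counts("gene1", "protein")
    return GammaFitReport(
        fit=gamma_fit(protein), true_shape=a_o * max_rcoil / d, true_scale=b_o,
        n_cells=n_cells, seed=seed,
    )


def run_gamma_error_scan(
    a_o_values: Sequence[float] | None = None,
    k1_values: Sequence[float] | None = None,
    n_cells: int = 2000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Percent error of the fitted gamma (shape, scale) over an (a_o, K1) grid.

    Long-format table: a_o, K1, pct_error_shape, pct_error_scale.
    """
    if a_o_values is None:
        a_o_values = np.linspace(10.0, 200.0, 8)
    if k1_values is None:
        k1_values = np.geomspace(1.0, 100.0, 8)
    rows = []
    for i, k1 in enumerate(k1_values):
        for j, a_o in enumerate(a_o_values):
            rep = run_gamma_fit_experiment(
                a_o=a_o, K1=k1, n_cells=n_cells, seed=_sub_seed(seed, i, j), **kwargs
            )
            rows.append(
                {"a_o": a_o, "K1": k1,
                 "pct_error_shape": rep.pct_error_shape,
                 "pct_error_scale": rep.pct_error_scale}
            )
    return pd.DataFrame(rows)


def _linked_system(
    a_o_values: Sequence[float],
    genes_per_domain: int,
    max_rcoil: int,
    K1: float, K2: float, R: float, gamma: float, d: float, b_o: float,
) -> SystemSpec:
    domains = []
    for di in range(len(a_o_values) // genes_per_domain):
        genes = tuple(
            GeneSpec(name=f"gene{di * genes_per_domain + k + 1}",
                     a_o=a_o_values[di * genes_per_domain + k], b_o=b_o)
            for k in range(genes_per_domain)
        )
        domains.append(
            DomainSpec(name=f"domain{di + 1}", genes=genes, max_rcoil=max_rcoil,
                       K1=K1, K2=K2, R=R)
        )
    return SystemSpec(domains=tuple(domains), global_rates=GlobalRates(gamma=gamma, d=d))


@dataclass
class LinkedDomainReport:
    """Mean expression and pairwise correlations for genes sharing domains."""

    gene_names: list[str]
    domain_of_gene: dict[str, str]
    means: pd.DataFrame = field(repr=False)     # per gene: mRNA/protein mean + sem (+isolated)
    corr_mrna: pd.DataFrame = field(repr=False)
    corr_protein: pd.DataFrame = field(repr=False)
    n_cells: int = 0
    seed: int = 0

    def save(self, out_dir) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        self.means.to_csv(out_dir / "means.tsv", sep="\t")
        self.corr_mrna.to_csv(out_dir / "correlation_mrna.tsv", sep="\t")
        self.corr_protein.to_csv(out_dir / "correlation_protein.tsv", sep="\t")


def run_linked_domain_experiment(
    a_o_values: Sequence[float] = LINKED_DOMAIN_AO,
    genes_per_domain: int = 5,
    max_rcoil: int = 20,
    isolated_max_rcoil: int = 20,
    n_cells: int = 4000,
    seed: int = 0,
    K1: float = 10.0,
    K2: float = 35.0,
    R: float = 1000.0,
    gamma: float = 50.0,
    d: float = 1.0,
    b_o: float = 2.0,
    include_isolated: bool = True,
    burn_in: float = DEFAULT_BURN_IN,
) -> LinkedDomainReport:
    """Two five-gene linked domains sharing RCoil (capacity 20 each, i.e. four
    full transcriptions of every gene) versus isolated single-gene controls.

    The isolated control places each gene alone in a domain of the same
    physical capacity (``isolated_max_rcoil``, default the full loop capacity
    20): a gene "in its own supercoiling domain" still lives on the same-size
    DNA loop, it just does not share it.  A per-gene capacity share (e.g. 4)
    can be requested instead, but note that halving the control's capacity
    also throttles the control and can mask the suppression by neighbours.
    """
    spec = _linked_system(a_o_values, genes_per_domain, max_rcoil, K1, K2, R, gamma, d, b_o)
    net = build_network(spec)
    sample = sample_cells(net, n_cells, seed=seed, burn_in=burn_in)

    gene_names = [g.name for g in spec.genes]
    domain_of_gene = {g.name: dom.name for dom in spec.domains for g in dom.genes}
    mrna = pd.DataFrame({g: sample.gene_counts(g, "mrna") for g in gene_names})
    prot = pd.DataFrame({g: sample.gene_counts(g, "protein") for g in gene_names})
    means = pd.DataFrame(
        {
            "a_o": list(a_o_values),
            "mrna_mean": mrna.mean(), "mrna_sem": mrna.std(ddof=1) / np.sqrt(n_cells),
            "protein_mean": prot.mean(), "protein_sem": prot.std(ddof=1) / np.sqrt(n_cells),
        },
        index=gene_names,
    )
    if include_isolated:
        iso_m, iso_m_sem, iso_p, iso_p_sem = [], [], [], []
        for k, (name, a_o) in enumerate(zip(gene_names, a_o_values)):
            iso_spec = single_gene_system(
                a_o=a_o, b_o=b_o, max_rcoil=isolated_max_rcoil,
                K1=K1, K2=K2, R=R, gamma=gamma, d=d, name=name,
            )
            iso = sample_cells(
                build_network(iso_spec), n_cells, seed=_sub_seed(seed, 100 + k), burn_in=burn_in
            )
            m = iso.gene_counts(name, "mrna")
            p = iso.gene_counts(name, "protein")
            iso_m.append(m.mean()); iso_m_sem.append(m.std(ddof=1) / np.sqrt(n_cells))
            iso_p.append(p.mean()); iso_p_sem.append(p.std(ddof=1) / np.sqrt(n_cells))
        means["isolated_mrna_mean"] = iso_m
        means["isolated_mrna_sem"] = iso_m_sem
        means["isolated_protein_mean"] = iso_p
        means["isolated_protein_sem"] = iso_p_sem
    return LinkedDomainReport(
        gene_names=gene_names, domain_of_gene=domain_of_gene, means=means,
        corr_mrna=correlation_matrix(mrna), corr_protein=correlation_matrix(prot),
        n_cells=n_cells, seed=seed,
    )


@dataclass
class NegativeRegulationReport:
    """Per-gene mean mRNA before and after inhibiting the strongest promoter."""

    table: pd.DataFrame = field(repr=False)  # gene, a_o, before/after mean + sem
    inhibited_gene: str = "gene1"
    inhibition_factor: float = 0.0
    n_cells: int = 0
    seed: int = 0

    def save(self, out_dir) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "negative_regulation.tsv", sep="\t", index=False)


def run_negative_regulation_experiment(
    a_o_values: Sequence[float] = NEGATIVE_REGULATION_AO,
    max_rcoil: int = 20,
    n_cells: int = 4000,
    seed: int = 0,
    inhibition_factor: float = 0.0,
    inhibited_gene: int = 1,
    K1: float = 10.0,
    K2: float = 35.0,
    R: float = 1000.0,
    gamma: float = 50.0,
    d: float = 1.0,
    b_o: float = 2.0,
    burn_in: float = DEFAULT_BURN_IN,
) -> NegativeRegulationReport:
    """Single five-gene linked domain; the strongest promoter is inhibited by
    scaling its a_o by ``inhibition_factor`` (0 = full repression) and the
    paired per-gene mean mRNA is reported with Monte-Carlo standard errors.

    Both conditions use the same master seed, so inhibiting a zero-rate gene
    reproduces the baseline bit for bit.
    """
    a_o_values = list(a_o_values)
    inhibited = list(a_o_values)
    inhibited[inhibited_gene - 1] *= inhibition_factor
    rows = {}
    for label, aos in (("before", a_o_values), ("after", inhibited)):
        spec = _linked_system(aos, len(aos), max_rcoil, K1, K2, R, gamma, d, b_o)
        net = build_network(spec)
        sample = sample_cells(net, n_cells, seed=seed, burn_in=burn_in)
        for k, g in enumerate(spec.genes):
            m = sample.gene_counts(g.name, "mrna")
            rows.setdefault(g.name, {"gene": g.name, "a_o": a_o_values[k]})
            rows[g.name][f"{label}_mean"] = m.mean()
            rows[g.name][f"{label}_sem"] = m.std(ddof=1) / np.sqrt(n_cells)
    return NegativeRegulationReport(
        table=pd.DataFrame(rows.values()), inhibited_gene=f"gene{inhibited_gene}",
        inhibition_factor=inhibition_factor, n_cells=n_cells, seed=seed,
    )
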