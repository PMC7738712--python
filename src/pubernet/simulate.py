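"""Synthetic two-group expression studies with planted, known structure.

The generator emulates the design of a pre- vs post-pubertal heifer
muscle transcriptome experiment at desk scale: a log2-scale expression
matrix over two groups (default 5 PRE + 6 POST samples), a transcription
factor (TF) subset, and four kinds of planted signal that the downstream
stages are meant to recover:

* **DE genes** — group means differ by ``de_effect`` (log2 units, POST
  higher).
* **Differentially wired regulators** — TFs whose correlation with the
  planted DE target genes is ``+wiring_rho`` in PRE and ``-wiring_rho``
  in POST.  Realized through a per-group latent factor: regulators and
  targets both load ``sqrt(rho)`` on it, and the target loading flips
  sign after puberty, so the TF-target correlation flips exactly.
* **Hub genes** — star centers correlated (``hub_rho``, same sign) with
  ``hub_degree`` partner genes in *both* groups.  The default star is
  wide (half the benchmark network) at a moderate ``hub_rho`` = 0.55:
  partner-partner correlations (``rho**2`` ~ 0.3) then fall below the
  PCIT trio tolerance and are pruned as hub-mediated, so the star
  center — not the blob of its partners — dominates the degree
  distribution.  With ``hubs_from_tfs=True`` hubs and partners are
  drawn from the TF block instead, so they survive into a pipeline
  network restricted to DE genes plus TFs.
* **Silent genes** — RPKM drawn uniformly below the 0.2 noise floor, to
  exercise the expression filter boundary.

Everything else is independent Gaussian noise on the log2 scale.
Expression is generated directly on the log2 scale (a multivariate
normal per group) so the planted correlation structure is exact;
``2**x`` converts to RPKM when the filter path is exercised.  All
generators are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import networkx as nx
import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator (defaults = the
    benchmark conditions used throughout the test-suite)."""

    n_genes: int = 200
    n_tf: int = 30
    n_samples_pre: int = 5
    n_samples_post: int = 6
    n_de: int = 20
    de_effect: float = 2.0
    n_regulators: int = 3
    wiring_targets_per_regulator: int = 20
    wiring_rho: float = 0.8
    regulator_loading: float = 0.95
    n_hubs: int = 1
    hub_degree: int = 100
    hub_rho: float = 0.55
    noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (2.0, 8.0)
    frac_silent: float = 0.1
    hubs_from_tfs: bool = False
    corrupt_sample: bool = False
    corrupt_shift: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (0 < self.n_tf <= self.n_genes):
            raise ValueError("n_tf must satisfy 0 < n_tf <= n_genes")
        if self.n_samples_pre <= 0 or self.n_samples_post <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_de < 0 or self.n_de + self.n_hubs > self.n_genes:
            raise ValueError("violated: n_de + n_hubs <= n_genes")
        if self.n_regulators > self.n_tf:
            raise ValueError("violated: n_regulators <= n_tf")
        if self.noise_sd < 0:
            raise ValueError("violated: noise_sd >= 0")
        if not (0 <= self.frac_silent <= 1):
            raise ValueError("frac_silent must lie in [0, 1]")
        if not (0 <= abs(self.wiring_rho) < 1) or not (0 <= abs(self.hub_rho) < 1):
            raise ValueError("wiring_rho and hub_rho must lie in (-1, 1)")
        if not (0 < self.regulator_loading <= 1):
            raise ValueError("regulator_loading must lie in (0, 1]")
        if abs(self.wiring_rho) > self.regulator_loading:
            raise ValueError("wiring_rho cannot exceed regulator_loading")
        if self.wiring_targets_per_regulator > max(self.n_de, 0) and self.n_regulators:
            raise ValueError(
                "wiring_targets_per_regulator cannot exceed n_de (targets are DE genes)"
            )
        if self.hubs_from_tfs:
            need = self.n_regulators + self.n_hubs * (1 + self.hub_degree)
            if need > self.n_tf:
                raise ValueError(
                    f"TF block too small: need {need} TFs for regulators + hub stars, "
                    f"have n_tf={self.n_tf}"
                )
        else:
            need = self.n_de + self.n_hubs * (1 + self.hub_degree)
            if self.n_tf + need > self.n_genes:
                raise ValueError("not enough non-TF genes for DE + hub stars")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated matrix."""

    gene_ids: list[str]
    tf_ids: list[str]
    de_gene_ids: list[str]
    regulator_ids: list[str]
    hub_ids: list[str]
    hub_partners: dict[str, list[str]] = field(default_factory=dict)
    wiring_target_ids: list[str] = field(default_factory=list)
    silent_ids: list[str] = field(default_factory=list)
    group_means: pd.DataFrame | None = None  # columns pre_mean, post_mean


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i + 1:04d}" for i in range(config.n_tf)]
    others = [f"G{i + 1:05d}" for i in range(config.n_genes - config.n_tf)]
    return tfs, others


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a log2-scale matrix, sample metadata and planted truth.

    Returns ``(expr, meta, truth)`` where ``meta`` has one row per sample
    with columns ``animal``, ``tissue``, ``library``, ``group``
    (library == sample, as when each sample is its own sequencing
    library).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tfs, others = _gene_names(config)
    gene_ids = tfs + others
    n1, n2 = config.n_samples_pre, config.n_samples_post
    samples = [f"PRE{i + 1}" for i in range(n1)] + [f"POST{i + 1}" for i in range(n2)]

    # --- role assignment (deterministic given the ID layout) ---
    regulators = tfs[: config.n_regulators]
    de_genes = others[: config.n_de] if config.de_effect != 0 else []
    wiring_targets = others[: config.wiring_targets_per_regulator] if config.n_regulators else []
    hub_pool = (
        tfs[config.n_regulators :]
        if config.hubs_from_tfs
        else others[config.n_de + config.wiring_targets_per_regulator :]
    )
    hubs: list[str] = []
    hub_partners: dict[str, list[str]] = {}
    pos = 0
    for _ in range(config.n_hubs):
        h = hub_pool[pos]
        partners = hub_pool[pos + 1 : pos + 1 + config.hub_degree]
        hubs.append(h)
        hub_partners[h] = list(partners)
        pos += 1 + config.hub_degree
    structured = set(regulators) | set(others[: config.n_de]) | set(wiring_targets)
    structured |= set(hubs) | {p for ps in hub_partners.values() for p in ps}
    free = [g for g in others if g not in structured]
    n_silent = int(round(config.frac_silent * config.n_genes))
    if n_silent > len(free):
        raise ValueError("frac_silent too large for the unstructured gene pool")
    silent = free[-n_silent:] if n_silent else []

    lo, hi = config.baseline_mean_range
    base = pd.Series(rng.uniform(lo, hi, size=config.n_genes), index=gene_ids)
    # signed DE shift applied to POST; all planted genes shift upward
    shift = pd.Series(0.0, index=gene_ids)
    for g in others[: config.n_de]:
        shift[g] = config.de_effect

    sd = config.noise_sd
    rho_w, rho_h = config.wiring_rho, config.hub_rho
    values = np.empty((config.n_genes, n1 + n2))
    idx = {g: i for i, g in enumerate(gene_ids)}

    for group, cols, target_sign in (("PRE", range(0, n1), +1.0), ("POST", range(n1, n1 + n2), -1.0)):
        m = len(list(cols))
        cols = np.asarray(list(cols))
        latent = rng.standard_normal(m)  # shared wiring factor for this group
        z = rng.standard_normal((config.n_genes, m))
        block = np.empty((config.n_genes, m))
        # regulator/target factor loadings chosen so the TF-target
        # correlation is exactly +-wiring_rho (a * b = rho)
        a_reg = config.regulator_loading
        b_tgt = rho_w / a_reg if a_reg else 0.0
        hub_z = {h: rng.standard_normal(m) for h in hubs}
        for g in gene_ids:
            i = idx[g]
            mu = base[g] + (shift[g] if group == "POST" else 0.0)
            if g in regulators:
                dev = a_reg * latent + np.sqrt(1 - a_reg**2) * z[i]
            elif g in wiring_targets:
                dev = target_sign * b_tgt * latent + np.sqrt(1 - b_tgt**2) * z[i]
            elif g in hubs:
                dev = hub_z[g]
            elif any(g in ps for ps in hub_partners.values()):
                h = next(h for h, ps in hub_partners.items() if g in ps)
                dev = rho_h * hub_z[h] + np.sqrt(1 - rho_h**2) * z[i]
            else:
                dev = z[i]
            block[i] = mu + sd * dev
        # silent genes: RPKM uniform below the 0.2 noise floor
        for g in silent:
            i = idx[g]
            block[i] = np.log2(rng.uniform(1e-3, 0.2, size=m))
        values[:, cols] = block

    if config.corrupt_sample:
        # shift the first PRE sample far from the cloud (faulty library)
        values[:, 0] += config.corrupt_shift * rng.uniform(0.5, 1.5, size=config.n_genes)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples), scale="log2"
    )
    meta = pd.DataFrame(
        {
            "animal": [f"A{i + 1:02d}" for i in range(n1 + n2)],
            "tissue": "muscle",
            "library": [f"L{i + 1:02d}" for i in range(n1 + n2)],
            "group": ["PRE"] * n1 + ["POST"] * n2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    group_means = pd.DataFrame(
        {"pre_mean": base, "post_mean": base + shift}, index=gene_ids
    )
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        tf_ids=tfs,
        de_gene_ids=de_genes,
        regulator_ids=regulators,
        hub_ids=hubs,
        hub_partners=hub_partners,
        wiring_target_ids=wiring_targets,
        silent_ids=silent,
        group_means=group_means,
    )
    return expr, meta, truth


def generate_ppi(
    truth: SyntheticTruth, background_edge_prob: float, seed: int
) -> nx.Graph:
    """Erdos-Renyi background over all genes plus guaranteed hub stars.

    Every planted hub receives edges to all its planted partners, so its
    degree is at least the configured hub degree regardless of the
    background density.  No self-loops, no duplicate edges.
    """
    if not (0 <= background_edge_prob <= 1):
        raise ValueError("background_edge_prob must lie in [0, 1]")
    n = len(truth.gene_ids)
    g = nx.fast_gnp_random_graph(n, background_edge_prob, seed=seed)
    g = nx.relabel_nodes(g, dict(enumerate(truth.gene_ids)))
    for hub, partners in truth.hub_partners.items():
        g.add_edges_from((hub, p) for p in partners)
    return g


def generate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int,
    set_size: int,
    enriched_overlap: int,
    seed: int,
) -> dict[str, list[str]]:
    """GMT-style gene sets with one set enriched for planted DE genes.

    The first set (``SET_ENRICHED``) contains ``enriched_overlap`` DE
    genes topped up with non-DE genes; the remaining sets are uniform
    draws from the non-DE pool.
    """
    if set_size > len(truth.gene_ids):
        raise ValueError("set_size exceeds the number of genes")
    if enriched_overlap > len(truth.de_gene_ids):
        raise ValueError("enriched_overlap exceeds the number of planted DE genes")
    if enriched_overlap > set_size:
        raise ValueError("enriched_overlap exceeds set_size")
    rng = np.random.default_rng(seed)
    de = list(truth.de_gene_ids)
    non_de = [g for g in truth.gene_ids if g not in set(de)]
    sets: dict[str, list[str]] = {}
    members = list(rng.choice(de, size=enriched_overlap, replace=False)) if enriched_overlap else []
    fill = rng.choice(non_de, size=set_size - enriched_overlap, replace=False)
    sets["SET_ENRICHED"] = sorted(members + list(fill))
    for k in range(1, n_sets):
        sets[f"SET{k:03d}"] = sorted(
            rng.choice(non_de, size=min(set_size, len(non_de)), replace=False)
        )
    return sets


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["baseline_mean_range"] = list(d["baseline_mean_range"])
    return d
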