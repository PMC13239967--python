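"""Donor-paired synthetic scRNA-seq cohorts with known decomposition truth.

The generator emulates the structure of a paired two-condition skin biopsy
cohort: each donor contributes one sample per condition; each sample draws a
cell-state composition from a condition-specific Dirichlet; each cell draws
gene counts from negative binomials whose means depend on its state and
condition. One designated marker gene (an F2RL1 surrogate at a fixed feature
index) carries the state x condition positivity signal; designated MT-/RPS-/
RPL-like gene blocks carry per-cell mitochondrial and ribosomal content so
that QC on gene-name prefixes operates as it would on real data.

The negative binomial is parameterized by mean ``mu`` and size ``theta``
with ``Var = mu + mu^2 / theta``, so the zero probability is
``(theta / (theta + mu)) ** theta`` and the marker-positive rate has the
closed form ``1 - (theta/(theta+mu))**theta`` used by the analytic truth.

No claim is made that real lymphedema skin follows these distributions; the
generator provides exact ground truth for validating the estimation
pipeline, not a model of the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from kerastate.decomposition import DecompositionResult, _decompose_arrays
from kerastate.errors import ConfigError, KerastateError

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "expected_decomposition",
    "write_cohort",
    "nb_positive_rate",
    "nb_mu_for_positive_rate",
    "default_config",
    "recovery_benchmark_config",
    "separation_benchmark_config",
]

#: Fixed feature index of the marker (F2RL1 surrogate).
MARKER_GENE_INDEX = 0
MARKER_GENE_NAME = "F2RL1"

#: Realistic names for the keratinocyte signature block (keratins and
#: cornification genes), used when the block is 20 genes or fewer.
_KERATIN_NAMES = [
    "KRT5", "KRT14", "KRT1", "KRT10", "KRT6A", "KRT6B", "KRT16", "KRT17",
    "DSP", "PKP1", "KRT15", "KRTDAP", "SBSN", "DMKN", "LGALS7", "S100A2",
    "FLG", "IVL", "LOR", "TP63",
]


def nb_positive_rate(mu: float, theta: float) -> float:
    """P(X > 0) for NB(mean mu, size theta): 1 - (theta/(theta+mu))**theta."""
    mu = np.asarray(mu, dtype=float)
    return 1.0 - (theta / (theta + mu)) ** theta


def nb_mu_for_positive_rate(rate: float, theta: float) -> float:
    """Invert the NB zero probability: the mean giving P(X > 0) = rate."""
    rate = np.asarray(rate, dtype=float)
    if np.any((rate < 0) | (rate >= 1)):
        raise ValueError("positive rate must lie in [0, 1)")
    return theta * ((1.0 - rate) ** (-1.0 / theta) - 1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic paired cohort.

    ``composition_alpha`` and ``marker_mu`` map each condition to a vector
    over ``state_names``; Dirichlet concentrations govern donor-to-donor
    compositional variability (larger = more similar donors). Gene layout is
    fixed: the marker gene sits at index 0, followed by ``n_mito_genes``
    MT-like genes, ``n_ribo_genes`` RPS/RPL-like genes, then the
    keratinocyte-signature block and per-state signature blocks; remaining
    indices are background. Per-cell mitochondrial and ribosomal content
    fractions are Beta-distributed and realized by diverting that share of
    the cell's expected library into the MT/ribosomal blocks.
    """

    n_donors: int = 3
    cells_per_sample: int = 1000
    n_genes: int = 200
    state_names: tuple[str, ...] = ("K0", "K3", "K6", "K8")
    conditions: tuple[str, str] = ("normal", "LE")
    composition_alpha: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"normal": (45.0, 30.0, 15.0, 10.0), "LE": (39.0, 38.0, 13.0, 10.0)}
    )
    marker_mu: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"normal": (0.9, 0.6, 0.8, 0.4), "LE": (0.8, 0.55, 0.5, 0.2)}
    )
    marker_dispersion: float = 2.0
    library_size_lognormal: tuple[float, float] = (0.0, 0.25)
    mito_fraction_beta: tuple[float, float] = (2.5, 35.0)
    ribo_fraction_beta: tuple[float, float] = (3.0, 12.0)
    background_gene_mu: float = 2.0
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    state_signature_genes: Mapping[str, Sequence[int]] | None = None
    signature_fold: float = 6.0
    keratinocyte_states: tuple[str, ...] | None = None
    keratinocyte_signature_genes: Sequence[int] = ()
    seed: int = 0

    def __post_init__(self):
        # canonicalize container types so configs compare and round-trip
        for name in ("composition_alpha", "marker_mu"):
            value = {c: tuple(float(x) for x in v) for c, v in getattr(self, name).items()}
            object.__setattr__(self, name, value)
        object.__setattr__(
            self, "keratinocyte_signature_genes",
            tuple(int(g) for g in self.keratinocyte_signature_genes),
        )
        if self.state_signature_genes is not None:
            object.__setattr__(
                self, "state_signature_genes",
                {s: tuple(int(g) for g in v) for s, v in self.state_signature_genes.items()},
            )
        for name in ("library_size_lognormal", "mito_fraction_beta", "ribo_fraction_beta"):
            object.__setattr__(self, name, tuple(float(x) for x in getattr(self, name)))
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.keratinocyte_states is not None:
            object.__setattr__(self, "keratinocyte_states", tuple(self.keratinocyte_states))

    # -- derived layout -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def mito_gene_indices(self) -> np.ndarray:
        return np.arange(1, 1 + self.n_mito_genes)

    @property
    def ribo_gene_indices(self) -> np.ndarray:
        start = 1 + self.n_mito_genes
        return np.arange(start, start + self.n_ribo_genes)

    @property
    def keratinocyte_state_names(self) -> tuple[str, ...]:
        return self.state_names if self.keratinocyte_states is None else self.keratinocyte_states

    def signature_map(self) -> dict[str, np.ndarray]:
        """Per-state signature gene indices; defaults to disjoint blocks
        after the reserved (marker/MT/ribosomal/keratinocyte) genes."""
        if self.state_signature_genes is not None:
            return {s: np.asarray(v, dtype=int) for s, v in self.state_signature_genes.items()}
        reserved = 1 + self.n_mito_genes + self.n_ribo_genes + len(self.keratinocyte_signature_genes)
        per_state = max((self.n_genes - reserved) // (2 * self.n_states), 1)
        out = {}
        for i, s in enumerate(self.state_names):
            start = reserved + i * per_state
            out[s] = np.arange(start, min(start + per_state, self.n_genes))
        return out

    def gene_names(self) -> list[str]:
        names = [f"GENE{i:04d}" for i in range(self.n_genes)]
        names[MARKER_GENE_INDEX] = MARKER_GENE_NAME
        for j, g in enumerate(self.mito_gene_indices):
            names[g] = f"MT-SIM{j + 1}"
        for j, g in enumerate(self.ribo_gene_indices):
            prefix = "RPS" if j % 2 == 0 else "RPL"
            names[g] = f"{prefix}SIM{j + 1}"
        krt = list(self.keratinocyte_signature_genes)
        for j, g in enumerate(krt):
            names[g] = _KERATIN_NAMES[j] if len(krt) <= len(_KERATIN_NAMES) else f"KRTSIM{j + 1}"
        return names

    # -- validation -----------------------------------------------------
    def validate(self) -> "CohortConfig":
        if self.n_donors < 1:
            raise ConfigError("n_donors", "must be >= 1")
        if self.cells_per_sample < 1:
            raise ConfigError("cells_per_sample", "must be >= 1")
        if self.n_genes < 50:
            raise ConfigError("n_genes", "must be >= 50")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ConfigError("conditions", "exactly two distinct conditions required")
        if len(set(self.state_names)) != self.n_states or self.n_states == 0:
            raise ConfigError("state_names", "must be non-empty and unique")
        for cond in self.conditions:
            alpha = np.asarray(self.composition_alpha.get(cond, ()), dtype=float)
            if alpha.shape != (self.n_states,):
                raise ConfigError("composition_alpha", f"condition {cond!r} needs {self.n_states} entries")
            if np.any(alpha <= 0):
                raise ConfigError("composition_alpha", "entries must be > 0")
            mu = np.asarray(self.marker_mu.get(cond, ()), dtype=float)
            if mu.shape != (self.n_states,):
                raise ConfigError("marker_mu", f"condition {cond!r} needs {self.n_states} entries")
            if np.any(mu < 0):
                raise ConfigError("marker_mu", "entries must be >= 0")
        if self.marker_dispersion <= 0:
            raise ConfigError("marker_dispersion", "theta must be > 0")
        if self.background_gene_mu < 0:
            raise ConfigError("background_gene_mu", "must be >= 0")
        for name in ("mito_fraction_beta", "ribo_fraction_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(name, "Beta parameters must be > 0")
        reserved_end = 1 + self.n_mito_genes + self.n_ribo_genes
        if reserved_end > self.n_genes:
            raise ConfigError("n_mito_genes", "marker + MT + ribosomal blocks exceed n_genes")
        special = set([MARKER_GENE_INDEX]) | set(self.mito_gene_indices) | set(self.ribo_gene_indices)
        krt = set(int(g) for g in self.keratinocyte_signature_genes)
        if krt & special:
            raise ConfigError("keratinocyte_signature_genes", "overlap marker/MT/ribosomal genes")
        if krt and (min(krt) < 0 or max(krt) >= self.n_genes):
            raise ConfigError("keratinocyte_signature_genes", "index out of range")
        for s, genes in self.signature_map().items():
            if s not in self.state_names:
                raise ConfigError("state_signature_genes", f"unknown state {s!r}")
            gset = set(int(g) for g in genes)
            if gset & (special | krt):
                raise ConfigError("state_signature_genes", f"state {s!r} overlaps reserved genes")
            if gset and (min(gset) < 0 or max(gset) >= self.n_genes):
                raise ConfigError("state_signature_genes", f"state {s!r} index out of range")
        if self.keratinocyte_states is not None:
            unknown = set(self.keratinocyte_states) - set(self.state_names)
            if unknown:
                raise ConfigError("keratinocyte_states", f"unknown states {sorted(unknown)}")
            if not self.keratinocyte_states:
                raise ConfigError("keratinocyte_states", "must name at least one state")
        if self.signature_fold < 1:
            raise ConfigError("signature_fold", "must be >= 1")
        return self

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_donors", "cells_per_sample", "n_genes", "marker_dispersion",
                "background_gene_mu", "n_mito_genes", "n_ribo_genes",
                "signature_fold", "seed",
            )
        }
        d["state_names"] = list(self.state_names)
        d["conditions"] = list(self.conditions)
        d["composition_alpha"] = {c: list(map(float, v)) for c, v in self.composition_alpha.items()}
        d["marker_mu"] = {c: list(map(float, v)) for c, v in self.marker_mu.items()}
        d["library_size_lognormal"] = list(self.library_size_lognormal)
        d["mito_fraction_beta"] = list(self.mito_fraction_beta)
        d["ribo_fraction_beta"] = list(self.ribo_fraction_beta)
        d["keratinocyte_states"] = (
            None if self.keratinocyte_states is None else list(self.keratinocyte_states)
        )
        d["keratinocyte_signature_genes"] = [int(g) for g in self.keratinocyte_signature_genes]
        d["state_signature_genes"] = (
            None
            if self.state_signature_genes is None
            else {s: [int(g) for g in v] for s, v in self.state_signature_genes.items()}
        )
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key in ("state_names", "conditions", "keratinocyte_states"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        for key in ("library_size_lognormal", "mito_fraction_beta", "ribo_fraction_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """A generated cohort: raw counts, per-cell truth, and analytic truth."""

    counts: sp.csr_matrix  # cells x genes, integer UMIs
    cells: pd.DataFrame  # barcode, donor, condition, true_state
    features: pd.DataFrame  # id, name
    truth: DecompositionResult
    config: CohortConfig


def expected_decomposition(config: CohortConfig) -> DecompositionResult:
    """Analytic decomposition implied by the configuration (no sampling).

    State proportions are the Dirichlet means restricted to keratinocyte
    states and renormalized (exact, by Dirichlet aggregation); per-state
    positive rates use the NB zero-probability closed form with the marker
    mean scaled by exp(library log-mean). Exact when the library log-sd is
    zero; with log-sd > 0 the realized rates deviate slightly (Jensen).
    """
    config.validate()
    cond_a, cond_b = config.conditions
    ker = list(config.keratinocyte_state_names)
    idx = [config.state_names.index(s) for s in ker]
    lib = float(np.exp(config.library_size_lognormal[0]))
    theta = config.marker_dispersion

    def cond_arrays(cond):
        alpha = np.asarray(config.composition_alpha[cond], dtype=float)[idx]
        pi = alpha / alpha.sum()
        mu = np.asarray(config.marker_mu[cond], dtype=float)[idx] * lib
        return pi, nb_positive_rate(mu, theta)

    pi_a, p_a = cond_arrays(cond_a)
    pi_b, p_b = cond_arrays(cond_b)
    return _decompose_arrays(ker, pi_a, p_a, pi_b, p_b, cond_a, cond_b, mode="expected")


def _sample_counts(config: CohortConfig, rng: np.random.Generator, states: np.ndarray, condition: str) -> np.ndarray:
    """Dense UMI counts for one sample's cells (rows follow ``states``)."""
    n_cells = states.size
    base = np.full((config.n_states, config.n_genes), config.background_gene_mu)
    sig = config.signature_map()
    krt = np.asarray(config.keratinocyte_signature_genes, dtype=int)
    for i, s in enumerate(config.state_names):
        base[i, sig.get(s, np.empty(0, dtype=int))] *= config.signature_fold
        if krt.size and s in config.keratinocyte_state_names:
            base[i, krt] *= config.signature_fold
        base[i, MARKER_GENE_INDEX] = config.marker_mu[condition][i]
    mito, ribo = config.mito_gene_indices, config.ribo_gene_indices
    base[:, mito] = 0.0
    base[:, ribo] = 0.0

    mean = base[states]  # n_cells x n_genes
    other_total = mean.sum(axis=1)
    f_mt = rng.beta(*config.mito_fraction_beta, size=n_cells)
    f_rb = rng.beta(*config.ribo_fraction_beta, size=n_cells)
    # keep the diverted share below the whole library
    excess = f_mt + f_rb
    shrink = np.where(excess > 0.9, 0.9 / excess, 1.0)
    f_mt, f_rb = f_mt * shrink, f_rb * shrink
    rest = 1.0 - f_mt - f_rb
    if mito.size:
        mean[:, mito] = (f_mt / rest * other_total / mito.size)[:, None]
    if ribo.size:
        mean[:, ribo] = (f_rb / rest * other_total / ribo.size)[:, None]

    log_mu, log_sd = config.library_size_lognormal
    lib = np.exp(rng.normal(log_mu, log_sd, size=n_cells)) if log_sd > 0 else np.full(n_cells, np.exp(log_mu))
    mean *= lib[:, None]

    theta = config.marker_dispersion
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full paired cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    blocks, rows = [], []
    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    for donor in donors:
        for cond in config.conditions:
            alpha = np.asarray(config.composition_alpha[cond], dtype=float)
            pi = rng.dirichlet(alpha)
            counts_per_state = rng.multinomial(config.cells_per_sample, pi)
            states = np.repeat(np.arange(config.n_states), counts_per_state)
            rng.shuffle(states)
            blocks.append(_sample_counts(config, rng, states, cond))
            for j, s in enumerate(states):
                rows.append(
                    {
                        "barcode": f"{donor}-{cond}-{j:05d}",
                        "donor": donor,
                        "condition": cond,
                        "true_state": config.state_names[s],
                    }
                )
    if blocks:
        counts = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
    else:  # 0-donor edge case never passes validate; kept for 0-cell writes
        counts = sp.csr_matrix((0, config.n_genes), dtype=np.int64)
    cells = pd.DataFrame(rows, columns=["barcode", "donor", "condition", "true_state"])
    names = config.gene_names()
    features = pd.DataFrame({"id": [f"SIM{i:05d}" for i in range(config.n_genes)], "name": names})
    return SyntheticCohort(
        counts=counts,
        cells=cells,
        features=features,
        truth=expected_decomposition(config),
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the 10x-style triple plus cells.tsv.

    matrix.mtx is MatrixMarket coordinate integer in genes x cells
    orientation (as Cell Ranger writes it); features.tsv holds (id, name);
    barcodes.tsv one barcode per line; cells.tsv the per-cell truth table.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.mtx",
        "features": directory / "features.tsv",
        "barcodes": directory / "barcodes.tsv",
        "cells": directory / "cells.tsv",
    }
    try:
        scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(cohort.counts.T), field="integer")
        cohort.features.to_csv(paths["features"], sep="\t", header=False, index=False)
        cohort.cells[["barcode"]].to_csv(paths["barcodes"], sep="\t", header=False, index=False)
        cohort.cells.to_csv(paths["cells"], sep="\t", index=False)
    except OSError as exc:
        raise KerastateError(f"write_cohort: cannot write to {directory}: {exc}") from exc
    return paths


# ----------------------------------------------------------------------
# Preset configurations
# ----------------------------------------------------------------------

def _marker_mu_map(rates: Mapping[str, Sequence[float]], theta: float) -> dict[str, tuple[float, ...]]:
    return {c: tuple(float(nb_mu_for_positive_rate(r, theta)) for r in v) for c, v in rates.items()}


def default_config(seed: int = 0) -> CohortConfig:
    """Paired 3-donor cohort emulating the observed lymphedema skin pattern.

    Four keratinocyte states (basal K0, differentiating K3, proliferative
    K6, stress-response K8) plus one non-keratinocyte immune-like state.
    Compositions and marker rates are set so the analytic truth reproduces
    the observed headline pattern: overall marker-positive keratinocyte
    fraction 41.6% (normal) vs 36.4% (LE), split into a -4.62 pp
    within-state component and a -0.62 pp composition component, with K3
    expanding, K0 contracting, and K6/K8 losing positivity most.
    """
    theta = 2.0
    # keratinocyte state proportions (renormalized over K states)
    pi = {"normal": np.array([0.45, 0.30, 0.15, 0.10]), "LE": np.array([0.39, 0.38, 0.13, 0.10])}
    # per-state positive rates solving P_normal=.416, within=-.0462, comp=-.0062
    rates = {
        "normal": (143 / 300, 0.365, 0.43, 0.275),
        "LE": (133 / 300, 0.355, 0.31, 0.155),
    }
    imm_frac, conc = 0.15, 100.0
    alpha = {
        c: tuple(conc * np.append((1 - imm_frac) * pi[c], imm_frac))
        for c in ("normal", "LE")
    }
    mu = _marker_mu_map({c: tuple(rates[c]) + (0.05,) for c in rates}, theta)
    return CohortConfig(
        n_donors=3,
        cells_per_sample=1500,
        n_genes=400,
        state_names=("K0", "K3", "K6", "K8", "IMM"),
        composition_alpha=alpha,
        marker_mu=mu,
        marker_dispersion=theta,
        library_size_lognormal=(0.0, 0.25),
        keratinocyte_states=("K0", "K3", "K6", "K8"),
        keratinocyte_signature_genes=tuple(range(31, 51)),
        signature_fold=6.0,
        seed=seed,
    ).validate()


def recovery_benchmark_config(seed: int = 0) -> CohortConfig:
    """10-donor, 2000-cells-per-sample cohort for parameter recovery.

    Configured truth: within-state component exactly -5 pp (a uniform
    -0.05 shift in every state's positive rate) and composition component
    exactly -1 pp. Library scaling is disabled and Dirichlet concentration
    set high so the analytic truth is exact and donor compositional noise
    does not swamp the estimand at this cohort size.
    """
    theta = 2.0
    rates = {
        "normal": (0.45, 0.40, 0.50, 0.55),
        "LE": (0.40, 0.35, 0.45, 0.50),
    }
    conc = 1000.0
    alpha = {
        "normal": tuple(conc * np.array([0.40, 0.30, 0.20, 0.10])),
        "LE": tuple(conc * np.array([0.45, 0.35, 0.15, 0.05])),
    }
    return CohortConfig(
        n_donors=10,
        cells_per_sample=2000,
        n_genes=60,
        state_names=("K0", "K3", "K6", "K8"),
        composition_alpha=alpha,
        marker_mu=_marker_mu_map(rates, theta),
        marker_dispersion=theta,
        library_size_lognormal=(0.0, 0.0),
        n_mito_genes=5,
        n_ribo_genes=10,
        signature_fold=4.0,
        seed=seed,
    ).validate()


def separation_benchmark_config(seed: int = 0, signature_fold: float = 4.0) -> CohortConfig:
    """Well-separated 4-state keratinocyte cohort plus an immune-like state,
    for clustering / annotation recovery tests (3 donors x 500 cells)."""
    theta = 2.0
    rates = {"normal": (0.45, 0.40, 0.50, 0.35, 0.05), "LE": (0.40, 0.38, 0.40, 0.30, 0.05)}
    alpha = {
        "normal": (30.0, 25.0, 15.0, 10.0, 15.0),
        "LE": (28.0, 27.0, 15.0, 10.0, 15.0),
    }
    return CohortConfig(
        n_donors=3,
        cells_per_sample=500,
        n_genes=300,
        state_names=("K0", "K3", "K6", "K8", "IMM"),
        composition_alpha=alpha,
        marker_mu=_marker_mu_map(rates, theta),
        marker_dispersion=theta,
        library_size_lognormal=(0.0, 0.2),
        keratinocyte_states=("K0", "K3", "K6", "K8"),
        keratinocyte_signature_genes=tuple(range(31, 51)),
        signature_fold=signature_fold,
        seed=seed,
    ).validate()
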