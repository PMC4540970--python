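"""Synthetic multi-temperature RNA-seq data with known reaction-norm structure.

The generator emulates the study design every downstream stage expects:
libraries at four developmental temperatures (13, 18, 23, 29 °C) with
replication, negative-binomial counts whose log2 means follow a linear or
quadratic function of temperature, library-size and (optionally) RNA
composition differences between libraries, and a matched per-gene
regulatory-architecture table whose TF / microRNA counts covary with the
plasticity class and with the gene's expression dynamics (SOC).

Every generating parameter is recorded in a per-gene truth table so that
normalization, model selection, classification and linkage can all be
validated against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountMatrix

__all__ = [
    "TRUE_CLASSES",
    "DEFAULT_CLASS_PROPORTIONS",
    "SimulationConfig",
    "simulate_counts",
    "simulate_architecture",
    "simulate_annotation",
    "true_log2_profile",
    "write_truth_tsv",
    "write_architecture_tsv",
]

TRUE_CLASSES = (
    "conserved",
    "increasing-linear",
    "increasing-quadratic",
    "decreasing-linear",
    "decreasing-quadratic",
    "U",
    "bell",
)

# Class mix of the fly experiment (9,995 expressed genes): 1,667 conserved,
# 1,403 / 1,947 increasing (linear / quadratic), 1,892 / 1,538 decreasing,
# 818 U-shaped, 730 bell-shaped.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "conserved": 1667 / 9995,
    "increasing-linear": 1403 / 9995,
    "increasing-quadratic": 1947 / 9995,
    "decreasing-linear": 1892 / 9995,
    "decreasing-quadratic": 1538 / 9995,
    "U": 818 / 9995,
    "bell": 730 / 9995,
}

_MIN_LOG2_RANGE = np.log2(1.5) * 1.05  # plastic classes clear the 1.25-fold call with margin


@dataclass
class SimulationConfig:
    """Parameters of the count simulator.

    Attributes
    ----------
    n_genes, n_replicates
        Number of genes and libraries per temperature. Six replicates per
        temperature by default: the experiment pooled two reciprocal crosses
        with three replicates each into a single analysis.
    temperatures
        Developmental temperatures in °C, strictly increasing.
    class_proportions
        Fraction of genes per true class; must sum to 1.
    baseline_log2_mean_range
        Range of the per-gene mean log2 relative expression (arbitrary
        units; columns are renormalized to the library size).
    effect_size_g1
        Magnitude scale of linear slopes, log2 units per °C.
    effect_size_g2
        Magnitude scale of quadratic coefficients, log2 units per °C².
    dispersion
        NB dispersion φ (variance = μ + φμ²), shared across genes. φ = 0 is
        a deterministic mode: counts are the rounded means, no sampling.
    library_size_range
        Total counts per library, drawn log-uniformly.
    composition_shift
        Fraction of genes spiked ``composition_shift_factor``-fold in the
        first library only, to exercise TMM's composition correction.
    """

    n_genes: int = 2000
    temperatures: tuple[float, ...] = (13.0, 18.0, 23.0, 29.0)
    n_replicates: int = 6
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    effect_size_g1: float = 0.1
    effect_size_g2: float = 0.02
    dispersion: float = 0.05
    library_size_range: tuple[float, float] = (5e5, 2e6)
    composition_shift: float = 0.0
    composition_shift_factor: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        temps = np.asarray(self.temperatures, dtype=float)
        if len(temps) < 2 or not np.all(np.diff(temps) > 0):
            raise ValueError("temperatures must be strictly increasing")
        unknown = set(self.class_proportions) - set(TRUE_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_proportions: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0.0 <= self.composition_shift < 1.0):
            raise ValueError("composition_shift must be in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list) + "\n")


def _allocate_classes(n_genes: int, proportions: dict[str, float]) -> list[str]:
    """Largest-remainder allocation of genes to classes (deterministic)."""
    classes = [c for c in TRUE_CLASSES if proportions.get(c, 0.0) > 0]
    raw = np.array([proportions[c] * n_genes for c in classes])
    counts = np.floor(raw).astype(int)
    short = n_genes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    labels: list[str] = []
    for c, k in zip(classes, counts):
        labels.extend([c] * k)
    return labels


def true_log2_profile(coeffs: np.ndarray, temperatures: np.ndarray) -> np.ndarray:
    """Evaluate the noiseless log2 reaction norm b0 + b1·T + b2·T²."""
    T = np.asarray(temperatures, dtype=float)
    c = np.atleast_2d(coeffs)
    return c[:, [0]] + c[:, [1]] * T[None, :] + c[:, [2]] * T[None, :] ** 2


def _soc_from_profile(log2_means: np.ndarray, temperatures: np.ndarray, max_gap: float = 6.0) -> np.ndarray:
    temps = np.asarray(temperatures, dtype=float)
    diffs = np.abs(np.diff(log2_means, axis=1))
    include = np.diff(temps) <= max_gap + 1e-12
    return diffs[:, include].sum(axis=1)


def _draw_coefficients(
    labels: list[str], cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-gene (b0, b1, b2) in the standard basis, log2 scale.

    Plastic classes are guaranteed a noiseless fitted range of at least
    1.5-fold so that the truth label is unambiguous under the downstream
    classification rules; U/bell vertices sit in the interior (shrunk 10%
    from the two central temperatures) so the 80 % end-difference rule holds
    with margin.
    """
    temps = np.asarray(cfg.temperatures, dtype=float)
    t_min, t_max = temps[0], temps[-1]
    span = t_max - t_min
    t_center = temps.mean()
    lo_b, hi_b = cfg.baseline_log2_mean_range
    coeffs = np.zeros((len(labels), 3))

    # interior vertex window for U/bell: between the two middle temperatures
    mid_lo, mid_hi = temps[len(temps) // 2 - 1], temps[len(temps) // 2]
    pad = 0.1 * (mid_hi - mid_lo)
    v_lo, v_hi = mid_lo + pad, mid_hi - pad

    for i, lab in enumerate(labels):
        b0 = rng.uniform(lo_b, hi_b)
        if lab == "conserved":
            coeffs[i] = (b0, 0.0, 0.0)
            continue
        if lab.endswith("linear"):
            mag = max(rng.uniform(0.5, 1.0) * cfg.effect_size_g1, _MIN_LOG2_RANGE / span)
            slope = mag if lab.startswith("increasing") else -mag
            coeffs[i] = (b0 - slope * t_center, slope, 0.0)
            continue
        # quadratic shapes: f(T) = c ± m (T - v)²
        if lab in ("U", "bell"):
            v = rng.uniform(v_lo, v_hi)
            sign = 1.0 if lab == "U" else -1.0
        else:  # monotone quadratic: vertex just outside the temperature range
            increasing = lab.startswith("increasing")
            left_vertex = rng.random() < 0.5
            if left_vertex:
                v = rng.uniform(t_min - 3.0, t_min)
                sign = 1.0 if increasing else -1.0
            else:
                v = rng.uniform(t_max, t_max + 3.0)
                sign = -1.0 if increasing else 1.0
        dd = (temps - v) ** 2
        range_factor = dd.max() - dd.min()
        m = max(rng.uniform(0.5, 1.0) * cfg.effect_size_g2, _MIN_LOG2_RANGE / range_factor)
        b2 = sign * m
        c = b0 - b2 * dd.mean()  # anchor the across-temperature mean at b0
        coeffs[i] = (c + b2 * v**2, -2.0 * b2 * v, b2)
    return coeffs


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its ground-truth table.

    Returns the :class:`~thermonorm.data.CountMatrix` and a truth DataFrame
    indexed by gene id with columns ``true_class``, ``b0``, ``b1``, ``b2``
    (log2-scale polynomial in °C) and ``true_soc``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    temps = np.asarray(config.temperatures, dtype=float)

    labels = _allocate_classes(config.n_genes, config.class_proportions)
    labels = [labels[i] for i in rng.permutation(len(labels))]
    coeffs = _draw_coefficients(labels, config, rng)

    profile = true_log2_profile(coeffs, temps)  # (G, n_temps) log2 relative
    true_soc = _soc_from_profile(profile, temps)

    sample_temps = np.repeat(temps, config.n_replicates)
    replicates = np.tile(np.arange(1, config.n_replicates + 1), len(temps))
    lib_ids = [f"T{t:g}_r{r}" for t, r in zip(sample_temps, replicates)]
    n_libs = len(lib_ids)

    lo_L, hi_L = config.library_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo_L), np.log(hi_L), size=n_libs))

    temp_index = np.searchsorted(temps, sample_temps)
    rel = 2.0 ** profile[:, temp_index]  # (G, n_libs)
    if config.composition_shift > 0:
        n_spike = max(1, int(round(config.composition_shift * config.n_genes)))
        spiked = rng.choice(config.n_genes, size=n_spike, replace=False)
        rel[spiked, 0] *= config.composition_shift_factor
    # constant (library-independent) normalizer: per-library means keep the
    # generating temperature structure exactly, so reaction-norm parameters
    # remain identifiable given the nominal library sizes as offsets
    normalizer = rel.sum(axis=0).mean()
    mu = lib_sizes[None, :] * rel / normalizer

    if config.dispersion == 0:
        counts = np.round(mu).astype(np.int64)
    else:
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p).astype(np.int64)

    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=lib_ids)
    samples = pd.DataFrame(
        {
            "library_id": lib_ids,
            "temperature": sample_temps,
            "replicate": replicates,
            "library_size_nominal": lib_sizes,
        }
    ).set_index("library_id")
    truth = pd.DataFrame(
        {
            "true_class": labels,
            "b0": coeffs[:, 0],
            "b1": coeffs[:, 1],
            "b2": coeffs[:, 2],
            "true_soc": true_soc,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CountMatrix(counts_df, samples), truth


# --- regulatory architecture ------------------------------------------------

# direction-class means of the fly architecture table: TFs / microRNAs
# (counts of distinct regulators) and mean UTR / first-intron lengths (bp)
DEFAULT_CLASS_MEANS: dict[str, dict[str, float]] = {
    "decreasing": {"n_tfs": 11.7, "n_mirnas": 11.6, "utr5": 373.2, "utr3": 868.0, "intron1": 4078.2},
    "increasing": {"n_tfs": 18.2, "n_mirnas": 7.1, "utr5": 208.8, "utr3": 471.8, "intron1": 838.8},
    "conserved": {"n_tfs": 15.0, "n_mirnas": 9.5, "utr5": 295.0, "utr3": 680.0, "intron1": 2530.0},
    "U": {"n_tfs": 15.7, "n_mirnas": 8.8, "utr5": 284.5, "utr3": 624.2, "intron1": 2427.7},
    "bell": {"n_tfs": 15.7, "n_mirnas": 8.8, "utr5": 284.5, "utr3": 624.2, "intron1": 2427.7},
}
_LENGTH_SDLOG = {"utr5": 0.8, "utr3": 0.9, "intron1": 1.2}

_DIRECTION_OF_CLASS = {
    "conserved": "conserved",
    "increasing-linear": "increasing",
    "increasing-quadratic": "increasing",
    "decreasing-linear": "decreasing",
    "decreasing-quadratic": "decreasing",
    "U": "U",
    "bell": "bell",
}


def simulate_architecture(
    truth: pd.DataFrame,
    tf_effect: float = -0.3,
    mirna_effect: float = 0.3,
    class_means: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a regulatory-architecture table matched to a truth table.

    TF and microRNA counts are Poisson with class-dependent means,
    additionally coupled to the gene's true SOC on the log-rate scale:
    ``λ = class_mean · exp(effect · z)`` with ``z`` the standardized SOC.
    Negative ``tf_effect`` makes highly dynamic genes carry fewer TFs;
    positive ``mirna_effect`` gives them more microRNAs. UTR and
    first-intron lengths are log-normal with class-dependent means.
    """
    rng = np.random.default_rng(seed)
    means = class_means if class_means is not None else DEFAULT_CLASS_MEANS

    classes = truth["true_class"].to_numpy()
    unknown = set(classes) - set(_DIRECTION_OF_CLASS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    direction = np.array([_DIRECTION_OF_CLASS[c] for c in classes])
    missing = set(direction) - set(means)
    if missing:
        raise ValueError(f"class_means missing entries for: {sorted(missing)}")

    soc = truth["true_soc"].to_numpy(dtype=float)
    sd = soc.std()
    z = (soc - soc.mean()) / sd if sd > 0 else np.zeros_like(soc)

    mean_tf = np.array([means[d]["n_tfs"] for d in direction])
    mean_mir = np.array([means[d]["n_mirnas"] for d in direction])
    n_tfs = rng.poisson(mean_tf * np.exp(tf_effect * z))
    n_mirnas = rng.poisson(mean_mir * np.exp(mirna_effect * z))

    lengths = {}
    for feat, col in (("utr5", "utr5_len"), ("utr3", "utr3_len"), ("intron1", "intron1_len")):
        sdlog = _LENGTH_SDLOG[feat]
        target = np.array([means[d][feat] for d in direction])
        meanlog = np.log(target) - sdlog**2 / 2.0
        lengths[col] = np.round(rng.lognormal(meanlog, sdlog)).astype(np.int64)

    return pd.DataFrame(
        {"n_tfs": n_tfs, "n_mirnas": n_mirnas, **lengths},
        index=truth.index.copy(),
    )


def simulate_annotation(
    truth: pd.DataFrame,
    n_random_terms: int = 40,
    term_size_range: tuple[int, int] = (15, 120),
    n_spiked_per_class: int = 1,
    spike_purity: float = 0.9,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Build a gene↔term annotation with class-enriched spike-in terms.

    Random terms draw genes uniformly; each spiked term draws
    ``spike_purity`` of its genes from one plasticity class, providing a
    positive control for the enrichment stage.
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth.index)
    annotation: dict[str, set[str]] = {}
    lo, hi = term_size_range
    for i in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        annotation[f"GO:R{i + 1:04d}"] = set(members)
    for cls in sorted(truth["true_class"].unique()):
        pool = genes[truth["true_class"].to_numpy() == cls]
        for j in range(n_spiked_per_class):
            size = min(int(rng.integers(lo, hi + 1)), len(pool))
            n_in = int(round(spike_purity * size))
            members = set(rng.choice(pool, size=n_in, replace=False))
            others = genes[~np.isin(genes, list(members))]
            members |= set(rng.choice(others, size=size - n_in, replace=False))
            annotation[f"GO:S_{cls}_{j + 1}"] = members
    return annotation


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.rename_axis("gene_id").to_csv(path, sep="\t")


def write_architecture_tsv(arch: pd.DataFrame, path: str | Path) -> None:
    arch.rename_axis("gene_id").to_csv(path, sep="\t")
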