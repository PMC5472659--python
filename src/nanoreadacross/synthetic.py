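"""Synthetic nanoparticle datasets with the statistical structure the method assumes.

The generator emulates the shape of a gold/silver nanoparticle corona dataset:
~120 substances with a single-atom metal core, one or two small organic
coatings (thiols, acids, amines), a small block of measured physico-chemical
descriptors of which a known subset drives the endpoint, a wide block-correlated
proteomics-style block whose first block is tied to the endpoint, and a
continuous log2-scale endpoint with Gaussian noise.

Two pieces of realism matter for the method and are modelled explicitly:

* **Inter-correlated physico-chemical signal features.**  Measured particle
  properties (the hydrodynamic-diameter family, surface area, zeta potential)
  are strongly mutually correlated.  Signal features therefore share a latent
  factor (pairwise correlation ``signal_correlation``, default 0.5) and carry
  all-positive effect weights, so substances close in descriptor space are
  close in activity — the regime read-across assumes.
* **Block-correlated proteomics features** built from latent factors
  (within-block correlation 0.7), so feature selection and weighted-cosine
  behaviour on wide correlated blocks is exercised.

``generate_dataset`` returns the dataset plus a ground-truth dict recording
which features truly matter and the generating coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Dataset, DescriptorClass, dataset_from_frame, write_dataset

__all__ = ["SyntheticConfig", "generate_dataset", "DEFAULT_COATING_POOL"]

#: small thiols / acids / amines of coating-like size: (short code, SMILES)
DEFAULT_COATING_POOL: list[tuple[str, str]] = [
    ("MBA", "OC(=O)c1ccc(S)cc1"),          # mercaptobenzoic acid
    ("MUA", "OC(=O)CCCCCCCCCCS"),           # mercaptoundecanoic acid
    ("MHA", "OC(=O)CCCCCS"),                # mercaptohexanoic acid
    ("CIT", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),  # citrate
    ("DDT", "SCCCCCCCCCCCC"),               # dodecanethiol
    ("NT", "SCCCCCCCCC"),                   # nonanethiol
    ("AUT", "NCCCCCCCCCCCS"),               # aminoundecanethiol
    ("CYS", "NC(CS)C(=O)O"),                # cysteine
    ("MES", "OS(=O)(=O)CCS"),               # mercaptoethanesulfonate
    ("HDA", "NCCCCCCCCCCCCCCCC"),           # hexadecylamine
    ("ODA", "NCCCCCCCCCCCCCCCCCC"),         # octadecylamine
    ("SA", "OC(=O)CCCCCCCCCCCCCCCCC"),      # stearic acid
    ("MPA", "OC(=O)CCS"),                   # mercaptopropionic acid
    ("TGA", "OC(=O)CS"),                    # thioglycolic acid
    ("DCA", "OC(=O)CCCCCCCCCS"),            # mercaptodecanoic acid
    ("PEG", "OCCOCCOCCO"),                  # short ethylene-glycol oligomer
]

_CORES = [("G", "[Au]"), ("S", "[Ag]")]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic dataset generator (defaults = study conditions)."""

    n_substances: int = 120
    n_cores: int = 2
    coating_pool: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COATING_POOL)
    )
    n_pchem_signal: int = 8
    n_pchem_noise: int = 12
    n_proteomics: int = 200
    proteomics_block_size: int = 20
    proteomics_block_corr: float = 0.7
    #: all-positive linear coefficients of the signal features on the endpoint
    effect_weights: list[float] = field(
        default_factory=lambda: [0.60, 0.55, 0.55, 0.50, 0.50, 0.50, 0.48, 0.48]
    )
    #: pairwise correlation among signal features via a shared latent factor
    signal_correlation: float = 0.5
    core_effect: float = 1.0
    #: correlation of the informative proteomics block factor with the signal
    proteomics_signal_mix: float = 0.6
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    endpoint_name: str = "net_cell_association"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pchem_signal < 1:
            raise ValueError("n_pchem_signal must be >= 1")
        if len(self.effect_weights) != self.n_pchem_signal:
            raise ValueError("effect_weights must have n_pchem_signal entries")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.coating_pool:
            raise ValueError("coating pool must be nonempty")
        if not (1 <= self.n_cores <= len(_CORES)):
            raise ValueError(f"n_cores must be in [1, {len(_CORES)}]")


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, dict]:
    """Generate a synthetic dataset and its ground truth.

    The endpoint (log2 scale) is ``y = Σ w_j z_j + core_effect·[core=Au] +
    N(0, noise_sd)`` where the signal features ``z_j`` share a latent factor.
    The first proteomics block is generated from a factor mixed with the
    standardized signal so a known subset of proteomics features correlates
    with the endpoint.  Missing feature cells are masked at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_substances

    # composition: core + 1-2 coatings
    core_idx = rng.integers(0, config.n_cores, n)
    cores = {}
    coatings = {}
    ids = []
    for i in range(n):
        letter, smi = _CORES[int(core_idx[i])]
        n_coat = int(rng.integers(1, 3))
        picks = rng.choice(len(config.coating_pool), size=n_coat, replace=False)
        codes = [config.coating_pool[int(j)][0] for j in picks]
        sid = f"{letter}{i + 1:03d}.{'@'.join(codes)}"
        ids.append(sid)
        cores[sid] = smi
        coatings[sid] = [config.coating_pool[int(j)][1] for j in picks]

    # physico-chemical block: correlated signal features + independent noise
    rho = config.signal_correlation
    u = rng.standard_normal(n)
    eps = rng.standard_normal((n, config.n_pchem_signal))
    Z = np.sqrt(rho) * u[:, None] + np.sqrt(1.0 - rho) * eps
    noise_feats = rng.standard_normal((n, config.n_pchem_noise))

    w = np.asarray(config.effect_weights, dtype=float)
    core_term = config.core_effect * (core_idx == 0).astype(float)
    signal = Z @ w + core_term
    y = signal + rng.normal(0.0, config.noise_sd, n)

    # proteomics blocks from latent factors; block 1 mixed with the signal
    n_blocks = int(np.ceil(config.n_proteomics / config.proteomics_block_size))
    g = (signal - signal.mean()) / signal.std() if signal.std() > 0 else np.zeros(n)
    factors = rng.standard_normal((n, n_blocks))
    mix = config.proteomics_signal_mix
    factors[:, 0] = mix * g + np.sqrt(1.0 - mix**2) * factors[:, 0]
    loading = np.sqrt(config.proteomics_block_corr)
    prot = np.empty((n, config.n_proteomics))
    block_of = np.empty(config.n_proteomics, dtype=int)
    for j in range(config.n_proteomics):
        b = j // config.proteomics_block_size
        block_of[j] = b
        prot[:, j] = loading * factors[:, b] + np.sqrt(1.0 - loading**2) * rng.standard_normal(n)

    sig_names = [f"pchem_{j + 1:02d}" for j in range(config.n_pchem_signal)]
    noise_names = [
        f"pchem_{j + 1:02d}"
        for j in range(config.n_pchem_signal, config.n_pchem_signal + config.n_pchem_noise)
    ]
    prot_names = [f"prot_{j + 1:03d}" for j in range(config.n_proteomics)]

    X = np.hstack([Z, noise_feats, prot])
    columns = sig_names + noise_names + prot_names
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)
    features = pd.DataFrame(X, index=ids, columns=columns)
    endpoints = pd.Series(y, index=ids, name=config.endpoint_name)

    feature_classes = {f: DescriptorClass.PCHEM for f in sig_names + noise_names}
    feature_classes.update({f: DescriptorClass.PROTEOMICS for f in prot_names})
    dataset = dataset_from_frame(
        features, endpoints, feature_classes=feature_classes, cores=cores, coatings=coatings
    )

    ground_truth = {
        "endpoint": config.endpoint_name,
        "signal_features": sig_names,
        "noise_features": noise_names,
        "effect_weights": dict(zip(sig_names, w.tolist())),
        "core_effect": config.core_effect,
        "signal_correlation": rho,
        "informative_proteomics_block": [
            prot_names[j] for j in range(config.n_proteomics) if block_of[j] == 0
        ],
        "noise_sd": config.noise_sd,
        "noiseless_endpoint": dict(zip(ids, signal.tolist())),
    }
    return dataset, ground_truth


def write_synthetic(
    config: SyntheticConfig, dataset_path: str | Path, truth_path: str | Path | None = None
) -> tuple[Dataset, dict]:
    """Generate and write the dataset CSV plus the ground-truth JSON."""
    dataset, truth = generate_dataset(config)
    write_dataset(dataset, dataset_path)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return dataset, truth
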