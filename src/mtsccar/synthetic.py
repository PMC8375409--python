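"""Latent-factor synthetic data with known sparse loadings.

Every view is driven by one latent "disease course" vector l: subjects fall
into three equally sized classes whose latent centers are -5, 0 and 5 (unit
within-class sd).  The genotype view is X = l u' + E, each imaging modality
is Y_m = l v_m' + E, and every cognitive score is c = l + e, with all noise
entries iid N(0, sigma2).  The loading vectors u and v_m are sparse with a
contiguous block of nonzero entries, so support recovery is well defined.

Defaults follow the reference design: n = 90 subjects (30 per class),
p = 100 SNPs, q = 90 ROIs, M = 2 modalities, one cognitive score, and noise
variances swept over 1..10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GroupStructure, StudyDataset, standardize, _center

__all__ = [
    "SyntheticTruth",
    "make_loadings",
    "simulate",
    "make_group_structure",
    "write_dataset",
]

CLASS_CENTERS = (-5.0, 0.0, 5.0)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset.

    ``u_true`` is the SNP loading (length p); ``v_true`` holds one imaging
    loading per modality (each length q).  ``supports`` records the index
    sets of nonzero entries, keyed "u" and "v1".."vM".
    """

    u_true: np.ndarray
    v_true: list[np.ndarray]
    latent: np.ndarray | None = None
    class_labels: np.ndarray | None = None
    noise_variance: float | None = None
    seed: int | None = None
    supports: dict[str, np.ndarray] = field(default_factory=dict)

    def loading_items(self) -> list[tuple[str, np.ndarray]]:
        return [("u", self.u_true)] + [
            (f"v{m + 1}", v) for m, v in enumerate(self.v_true)
        ]


def _block_loading(
    dim: int, support_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    k = int(round(support_fraction * dim))
    if k < 1:
        raise ValueError(
            f"support_fraction {support_fraction} leaves no nonzero entry in "
            f"a length-{dim} loading"
        )
    start = int(rng.integers(0, dim - k + 1))
    w = np.zeros(dim)
    sign = rng.choice([-1.0, 1.0])
    w[start : start + k] = sign * rng.uniform(0.5, 1.0, size=k)
    return w, np.arange(start, start + k)


def make_loadings(
    p: int,
    q: int,
    M: int = 2,
    support_fraction: float = 0.2,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw sparse ground-truth loadings with contiguous nonzero blocks.

    Each vector carries one contiguous block covering ``support_fraction``
    of its length; block position is seed-dependent, magnitudes are uniform
    in [0.5, 1] with a single random sign per block.
    """
    if not 0 < support_fraction <= 1:
        raise ValueError("support_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    u, su = _block_loading(p, support_fraction, rng)
    vs, supports = [], {"u": su}
    for m in range(M):
        v, sv = _block_loading(q, support_fraction, rng)
        vs.append(v)
        supports[f"v{m + 1}"] = sv
    return SyntheticTruth(u_true=u, v_true=vs, seed=seed, supports=supports)


def simulate(
    n: int = 90,
    p: int = 100,
    q: int = 90,
    M: int = 2,
    sigma2: float = 1.0,
    n_cognitive: int = 1,
    support_fraction: float = 0.2,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    scale: bool = True,
) -> tuple[StudyDataset, SyntheticTruth]:
    """Simulate an aligned study dataset from the latent-factor model.

    Subjects are split into three equal classes with latent centers -5, 0
    and 5; every view is a rank-one signal in the latent vector plus iid
    Gaussian noise of variance ``sigma2``.  Pass a pre-built ``truth`` to
    reuse one set of loadings across noise levels (as in a noise sweep).
    With ``scale=True`` the returned views are standardized/centered, ready
    for the solver; the truth object always stores the raw loadings.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if n % 3 != 0:
        raise ValueError("n must be divisible into three equal classes")
    if truth is None:
        truth = make_loadings(p, q, M, support_fraction=support_fraction, seed=seed)
    rng = np.random.default_rng(seed)
    per = n // 3
    labels = np.repeat([0, 1, 2], per)
    centers = np.asarray(CLASS_CENTERS)[labels]
    latent = rng.normal(loc=centers, scale=1.0)
    sd = np.sqrt(sigma2)

    X = np.outer(latent, truth.u_true) + rng.normal(0.0, sd, size=(n, p))
    Ys = [
        np.outer(latent, v) + rng.normal(0.0, sd, size=(n, q)) for v in truth.v_true
    ]
    Z = latent[:, None] + rng.normal(0.0, sd, size=(n, n_cognitive))

    subj = [f"S{i + 1:04d}" for i in range(n)]
    snps = [f"rs{i + 1:04d}" for i in range(p)]
    gdf = pd.DataFrame(X, index=subj, columns=snps)
    rois = [f"roi{j + 1:03d}" for j in range(q)]
    ydfs = [pd.DataFrame(Y, index=subj, columns=rois) for Y in Ys]
    zdf = pd.DataFrame(Z, index=subj, columns=[f"score{c + 1}" for c in range(n_cognitive)])
    if scale:
        gdf = standardize(gdf)
        ydfs = [standardize(Y) for Y in ydfs]
        zdf = _center(zdf)

    dataset = StudyDataset(
        genotypes=gdf,
        modalities=ydfs,
        cognitive=zdf,
        class_labels=labels,
    )
    truth = SyntheticTruth(
        u_true=truth.u_true,
        v_true=truth.v_true,
        latent=latent,
        class_labels=labels,
        noise_variance=sigma2,
        seed=seed,
        supports=truth.supports,
    )
    return dataset, truth


def make_group_structure(
    truth: SyntheticTruth,
    n_background_groups: int = 8,
    aligned: bool = True,
    seed: int = 0,
) -> GroupStructure:
    """Partition SNP indices into contiguous blocks for the group penalty.

    With ``aligned=True`` the true support forms its own group and the
    remaining SNPs are split into ``n_background_groups`` contiguous
    blocks, so the group penalty agrees with the signal structure.  With
    ``aligned=False`` block boundaries are drawn at random, deliberately
    cutting across the support (for negative controls).
    """
    p = truth.u_true.shape[0]
    labels = np.empty(p, dtype=object)
    if aligned:
        support = truth.supports["u"]
        labels[support] = "signal"
        rest = np.setdiff1d(np.arange(p), support)
        for j, chunk in enumerate(np.array_split(rest, n_background_groups)):
            labels[chunk] = f"bg{j + 1}"
    else:
        rng = np.random.default_rng(seed)
        cuts = np.sort(rng.choice(np.arange(1, p), size=n_background_groups, replace=False))
        for j, chunk in enumerate(np.split(np.arange(p), cuts)):
            labels[chunk] = f"blk{j + 1}"
    return GroupStructure(labels=tuple(labels))


def write_dataset(
    dataset: StudyDataset, truth: SyntheticTruth, outdir: str | Path
) -> list[Path]:
    """Write the labeled-TSV trio plus a truth JSON; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index_label="id")
        paths.append(path)

    _write(dataset.genotypes, "genotypes.tsv")
    for m, Y in enumerate(dataset.modalities):
        _write(Y, f"modality{m + 1}.tsv")
    _write(dataset.cognitive, "cognitive.tsv")

    truth_path = outdir / "truth.json"
    payload = {
        "seed": truth.seed,
        "noise_variance": truth.noise_variance,
        "class_centers": list(CLASS_CENTERS),
        "u_true": truth.u_true.tolist(),
        "v_true": [v.tolist() for v in truth.v_true],
        "latent": None if truth.latent is None else truth.latent.tolist(),
        "class_labels": None
        if truth.class_labels is None
        else truth.class_labels.tolist(),
        "supports": {k: v.tolist() for k, v in truth.supports.items()},
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    paths.append(truth_path)
    return paths
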