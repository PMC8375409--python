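"""Structured sparsity penalties on the canonical weight matrices.

Three penalties are used.  The L2,1 norm (sum of row Euclidean norms)
couples the tasks: a SNP or ROI is kept or discarded jointly across
modalities.  The L1,1 norm (sum of absolute entries) enforces individual
element-level sparsity.  The group penalty sums, over SNP groups (genes or
LD blocks), the Frobenius norm of the weight sub-matrix of each group, so
SNPs sharing a group are selected or dropped as a unit; with singleton
groups it reduces to L2,1 and with one all-encompassing group to the
Frobenius norm.
"""

from __future__ import annotations

import numpy as np

from .datasets import GroupStructure

__all__ = ["penalty_l21", "penalty_l11", "penalty_group"]


def penalty_l21(W: np.ndarray) -> float:
    """Sum of Euclidean norms of the rows of ``W``."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    return float(np.linalg.norm(W, axis=1).sum())


def penalty_l11(W: np.ndarray) -> float:
    """Sum of absolute values of all entries of ``W``."""
    return float(np.abs(np.asarray(W, dtype=float)).sum())


def penalty_group(U: np.ndarray, groups: GroupStructure) -> float:
    """Sum over groups of the Frobenius norm of the group's rows of ``U``."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if groups.p != U.shape[0]:
        raise ValueError(
            f"group structure covers {groups.p} rows but U has {U.shape[0]}"
        )
    return float(
        sum(np.linalg.norm(U[idx, :]) for idx in groups.indices().values())
    )
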