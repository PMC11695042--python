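"""Block- and variable-level importance from a fitted multiblock PLS model.

Block importance on projection (BIP) weights each block's squared
super-weight by the squared covariance between response and super-score:

    BIP(c) = C * sum_r cov^2(y, t_r) w_r(c)^2 / sum_r cov^2(y, t_r)

Because the super-weights have unit norm, the mean of BIP over blocks is
exactly 1, which is what makes the ">1" cutoff meaningful.

The weighted variant BwIP further multiplies each term by the block's
mean-square within-block weight U_r(c) = ||u_r(c)||^2 / p_c, penalizing
blocks that spread their weight over many variables:

    BwIP(c) = C * sum_r cov^2(y, t_r) U_r(c) w_r(c)^2 / sum_r cov^2(y, t_r)

With unit-norm within-block weights U_r(c) = 1/p_c, so for equal-size
blocks BwIP = BIP / p_c: BwIP systematically favours small, concentrated
blocks and selects fewer of them than BIP.  A literal variant that drops
the covariance weighting from the numerator is available behind a flag.

Variable importance (VIP) uses per-variable composite weights
v_jr = w_r(c(j)) u_jr(c(j)) / l(c(j)), renormalized to unit norm per
component, with the usual explained-sum-of-squares weighting
SS_r = q_r^2 t_r' t_r:

    VIP_j = sqrt( p * sum_r SS_r v_jr^2 / sum_r SS_r )

so that sum_j VIP_j^2 = p and VIP > 1 flags above-average variables.  The
absolute loading weight of a variable is mean_r |v_jr|.  Selection rules
apply the conventional cutoffs (block statistics > 1, VIP > 1,
|loading| > 0.2); when nothing clears a cutoff, the top-ranked block (or
the top variable per retained block) is kept so the pipeline never dead-ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mbpls import MbplsModel

__all__ = [
    "ImportanceReport",
    "compute_bip",
    "compute_bwip",
    "compute_vip",
    "variable_loading_weights",
    "compute_importance",
    "select_blocks",
    "select_variables",
]


@dataclass
class ImportanceReport:
    """Per-block BIP/BwIP and per-variable VIP/|loading|, with the cutoffs used."""

    bip: np.ndarray
    bwip: np.ndarray
    vip: np.ndarray
    abs_loading_weight: np.ndarray
    variable_ids: list[str]
    block_labels: np.ndarray  # per-variable block label, 1..C
    block_threshold: float = 1.0
    vip_threshold: float = 1.0
    loading_threshold: float = 0.2

    @property
    def n_blocks(self) -> int:
        return self.bip.size


def _cov2_weights(model: MbplsModel) -> np.ndarray:
    if model.n_components < 1:
        raise ValueError("model has no effective components")
    cov2 = model.cov_yt**2
    if cov2.sum() <= 0:
        raise ValueError("all component covariances are zero; degenerate model")
    return cov2


def compute_bip(model: MbplsModel) -> np.ndarray:
    """Block importance on projection; entries average to 1 over blocks."""
    cov2 = _cov2_weights(model)
    return model.n_blocks * (model.W**2 @ cov2) / cov2.sum()


def _mean_square_u(model: MbplsModel) -> np.ndarray:
    """(C, R) matrix of U_r(c) = ||u_r(c)||^2 / p_c."""
    sizes = model.block_sizes.astype(float)
    return np.vstack(
        [(model.U[c] ** 2).sum(axis=0) / sizes[c] for c in range(model.n_blocks)]
    )


def compute_bwip(model: MbplsModel, literal: bool = False) -> np.ndarray:
    """Weighted block importance on projection.

    ``literal=False`` (default) keeps the covariance weighting in the
    numerator, so BwIP reduces to BIP / p_c for equal-size blocks.  With
    ``literal=True`` the numerator is the bare sum of U_r(c) w_r(c)^2 over
    components, divided by the summed squared covariances.
    """
    cov2 = _cov2_weights(model)
    uw2 = _mean_square_u(model) * model.W**2
    if literal:
        return model.n_blocks * uw2.sum(axis=1) / cov2.sum()
    return model.n_blocks * (uw2 @ cov2) / cov2.sum()


def _composite_weights(model: MbplsModel) -> np.ndarray:
    """(p, R) per-variable composite weights, unit-norm per component."""
    if model.n_components < 1:
        raise ValueError("model has no effective components")
    blocks = model.partition.blocks()
    sizes = model.block_sizes.astype(float)
    V = np.zeros((model.p, model.n_components))
    for c, idx in enumerate(blocks):
        scale = sizes[c] if model.block_size_normalization else 1.0
        V[idx, :] = model.U[c] * (model.W[c, :] / scale)
    norms = np.linalg.norm(V, axis=0)
    nz = norms > 0
    V[:, nz] = V[:, nz] / norms[nz]
    return V


def compute_vip(model: MbplsModel) -> np.ndarray:
    """Variable importance in projection; sum of squares equals p."""
    V = _composite_weights(model)
    ss = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)
    if ss.sum() <= 0:
        raise ValueError("all components explain zero response variance")
    return np.sqrt(model.p * (V**2 @ ss) / ss.sum())


def variable_loading_weights(model: MbplsModel) -> np.ndarray:
    """Per-variable mean over components of the absolute composite weight."""
    V = _composite_weights(model)
    return np.abs(V).mean(axis=1)


def compute_importance(
    model: MbplsModel,
    literal_bwip: bool = False,
    block_threshold: float = 1.0,
    vip_threshold: float = 1.0,
    loading_threshold: float = 0.2,
) -> ImportanceReport:
    """Assemble the full per-block and per-variable importance report."""
    return ImportanceReport(
        bip=compute_bip(model),
        bwip=compute_bwip(model, literal=literal_bwip),
        vip=compute_vip(model),
        abs_loading_weight=variable_loading_weights(model),
        variable_ids=list(model.variable_ids),
        block_labels=model.partition.labels.copy(),
        block_threshold=block_threshold,
        vip_threshold=vip_threshold,
        loading_threshold=loading_threshold,
    )


def _block_statistic(report: ImportanceReport, rule: str) -> np.ndarray:
    if rule == "bip":
        return report.bip
    if rule == "bwip":
        return report.bwip
    if rule == "both":
        return np.minimum(report.bip, report.bwip)
    raise ValueError("rule must be 'bip', 'bwip' or 'both'")


def select_blocks(report: ImportanceReport, rule: str = "both") -> list[int]:
    """Blocks (1-based labels) whose statistic exceeds the threshold.

    ``rule='both'`` requires BIP and BwIP both above the cutoff.  If no
    block passes, the single top-ranked block by the rule's statistic is
    returned so downstream stages always have something to work with.
    """
    stat = _block_statistic(report, rule)
    passing = np.flatnonzero(stat > report.block_threshold)
    if passing.size == 0:
        passing = np.array([int(np.argmax(stat))])
    return [int(c) + 1 for c in passing]


def select_variables(
    report: ImportanceReport,
    block_subset: list[int] | None = None,
    rule: str = "vip",
) -> list[int]:
    """Variable indices (into the report) passing the within-block cutoff.

    Only variables in ``block_subset`` (1-based labels; default all blocks)
    are considered.  ``rule='vip'`` keeps VIP > threshold, ``rule='loading'``
    keeps |loading| > threshold.  If a retained block contributes nothing,
    its top variable by the rule's statistic is kept as a fallback.
    """
    if rule == "vip":
        stat, thr = report.vip, report.vip_threshold
    elif rule == "loading":
        stat, thr = report.abs_loading_weight, report.loading_threshold
    else:
        raise ValueError("rule must be 'vip' or 'loading'")
    if block_subset is None:
        block_subset = sorted(set(int(b) for b in report.block_labels))
    chosen: list[int] = []
    for b in block_subset:
        members = np.flatnonzero(report.block_labels == b)
        if members.size == 0:
            raise ValueError(f"block {b} not present in report")
        passing = members[stat[members] > thr]
        if passing.size == 0:
            passing = members[[int(np.argmax(stat[members]))]]
        chosen.extend(int(j) for j in passing)
    return sorted(chosen)
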