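"""Adjoint absorption Jacobians, group aggregation, and channel ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward import CM_PER_MM, DetectorPatch, FemSystem, SourceSpec, solve
from .phantom import Channel, ChannelGroup, ProbeLayout, TetMesh

@dataclass
class JacobianMatrix:
    """Channel-by-node sensitivity d(Phi_i)/d(mua_j), s^-1 per cm^-1."""

    values: np.ndarray  # (num_channels, num_nodes), entries <= 0
    channels: list[Channel]
    wavelength: float
    phase: str
    fluences: np.ndarray  # clean channel fluence Phi_i, s^-1

    @property
    def num_channels(self) -> int:
        return self.values.shape[0]


def _adjoint_product(mesh: TetMesh, phi: np.ndarray,
                     psi: np.ndarray) -> np.ndarray:
    """d(psi^T K phi)/d(mua_j in mm^-1) under the lumped absorption mass.

    The lumped mass contributes V/20 * (sum_a mu_a + mu_a) to diagonal entry
    a of each element, so the derivative with respect to nodal mua_j is
    V/20 * (sum_a psi_a phi_a + psi_j phi_j) over elements containing j.
    """
    elems = mesh.elements
    prod = psi[elems] * phi[elems]  # (ne, 4)
    contrib = (prod.sum(axis=1, keepdims=True) + prod) * (
        mesh.element_volumes[:, None] / 20.0
    )
    return np.bincount(
        elems.ravel(), weights=contrib.ravel(), minlength=mesh.num_nodes
    )


def jacobian(
    system: FemSystem,
    sources: Sequence[SourceSpec],
    patches: Sequence[DetectorPatch],
    channels: Sequence[Channel],
) -> JacobianMatrix:
    """Adjoint-method absorption Jacobian for a set of channels.

    One forward solve per source actually referenced, one adjoint solve per
    referenced detector patch, then J_i = -psi_det^T dK/dmua phi_src per
    channel.  kappa is held at its baseline value (Born absorption
    sensitivity), matching the CW convention.
    """
    src_ids = sorted({ch.source_id for ch in channels})
    det_ids = sorted({ch.detector_id for ch in channels})
    for ch in channels:
        if ch.source_id >= len(sources) or ch.detector_id >= len(patches):
            raise IndexError(
                f"channel ({ch.source_id}, {ch.detector_id}) references an "
                "unknown optode"
            )
    phi = {s: solve(system, sources[s], source_id=s).phi for s in src_ids}
    psi = {
        d: system.solve_rhs(np.asarray(patches[d].weights.todense()).ravel())
        for d in det_ids
    }
    J = np.empty((len(channels), system.num_nodes))
    flu = np.empty(len(channels))
    for i, ch in enumerate(channels):
        # d/d(mua_cm) = CM_PER_MM * d/d(mua_mm)
        J[i] = -CM_PER_MM * _adjoint_product(
            system.mesh, phi[ch.source_id], psi[ch.detector_id]
        )
        flu[i] = float(
            (patches[ch.detector_id].weights @ phi[ch.source_id])[0]
        )
    return JacobianMatrix(
        values=J,
        channels=list(channels),
        wavelength=system.props.wavelength,
        phase=str(getattr(system.props.phase, "value", system.props.phase)),
        fluences=flu,
    )


@dataclass
class GroupSensitivityMap:
    """Per-node summed Jacobian normalized to unit maximum magnitude."""

    values: np.ndarray  # dimensionless, in [-1, 1]
    group_label: str
    wavelength: float


def total_normalized_jacobian(
    J: JacobianMatrix, group: ChannelGroup
) -> GroupSensitivityMap:
    """Sum member-channel rows and normalize by the peak magnitude."""
    if group.nm == 0:
        raise ValueError(f"channel group {group.label!r} is empty")
    idx = _member_rows(J, group)
    total = J.values[idx].sum(axis=0)
    peak = np.abs(total).max()
    if peak == 0:
        raise ValueError("summed Jacobian is identically zero")
    return GroupSensitivityMap(
        values=total / peak, group_label=group.label, wavelength=J.wavelength
    )


def _member_rows(J: JacobianMatrix, group: ChannelGroup) -> np.ndarray:
    key = {(c.source_id, c.detector_id): i for i, c in enumerate(J.channels)}
    try:
        return np.array(
            [key[(c.source_id, c.detector_id)] for c in group.channels]
        )
    except KeyError as exc:
        raise ValueError(f"group channel {exc} missing from Jacobian")


def brain_sensitivity_scores(
    J: JacobianMatrix, brain_nodes: np.ndarray
) -> np.ndarray:
    """Per-channel score: sum of |J_ij| over fetal-brain nodes."""
    brain_nodes = np.asarray(brain_nodes)
    if brain_nodes.size == 0:
        raise ValueError("brain node set is empty")
    return np.abs(J.values[:, brain_nodes]).sum(axis=1)


@dataclass(frozen=True)
class RankedChannel:
    rank: int
    channel: Channel
    score: float


@dataclass
class ChannelRanking:
    group_label: str
    wavelength: float
    entries: list[RankedChannel]

    def __len__(self) -> int:
        return len(self.entries)


def rank_top_channels(
    scores: np.ndarray,
    J: JacobianMatrix,
    group: ChannelGroup,
    k: int = 10,
) -> ChannelRanking:
    """Top-k member channels by brain score.

    Ties are broken deterministically: higher score first, then shorter
    distance, then lower row index.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if group.nm == 0:
        raise ValueError(f"channel group {group.label!r} is empty")
    idx = _member_rows(J, group)
    order = sorted(
        idx, key=lambda i: (-scores[i], J.channels[i].distance, i)
    )[: min(k, len(idx))]
    entries = [
        RankedChannel(rank=r + 1, channel=J.channels[i], score=float(scores[i]))
        for r, i in enumerate(order)
    ]
    return ChannelRanking(
        group_label=group.label, wavelength=J.wavelength, entries=entries
    )


@dataclass
class OrientedChannelRecord:
    rank: int
    source_position: np.ndarray
    detector_position: np.ndarray
    midpoint: np.ndarray
    distance: float
    group_label: str
    score: float
    peak_brain_node: int
    peak_brain_position: np.ndarray


def channel_orientation_map(
    ranking: ChannelRanking,
    layout: ProbeLayout,
    J: JacobianMatrix,
    brain_nodes: np.ndarray,
    mesh: TetMesh,
) -> list[OrientedChannelRecord]:
    """Geometry records for plotting ranked channels over the fetal head.

    Each record carries the channel endpoints plus the brain node where the
    channel's |J| peaks (the region the channel actually interrogates).
    """
    brain_nodes = np.asarray(brain_nodes)
    key = {(c.source_id, c.detector_id): i for i, c in enumerate(J.channels)}
    records = []
    for entry in ranking.entries:
        ch = entry.channel
        row = key[(ch.source_id, ch.detector_id)]
        peak_local = int(np.argmax(np.abs(J.values[row, brain_nodes])))
        peak = int(brain_nodes[peak_local])
        spos = layout.source_positions[ch.source_id]
        dpos = layout.detector_positions[ch.detector_id]
        records.append(
            OrientedChannelRecord(
                rank=entry.rank,
                source_position=spos,
                detector_position=dpos,
                midpoint=(spos + dpos) / 2.0,
                distance=ch.distance,
                group_label=ranking.group_label,
                score=entry.score,
                peak_brain_node=peak,
                peak_brain_position=mesh.nodes[peak],
            )
        )
    return records
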