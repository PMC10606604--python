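"""Motion asynchronization: pairwise NCC map and its mean.

The normalized correlation coefficient between the centered waveforms of
positions i and j is the zero-lag cosine similarity

    R_ij = sum_m z_i(t_m) z_j(t_m) / sqrt(sum_m z_i^2 sum_m z_j^2),

computed on already-centered waveforms (no re-centering here).  The NCC
map is the symmetric N x N matrix of all pairs; synchronized diaphragm
motion gives values near 1 everywhere, regional asynchrony (e.g.
paradoxical anterior motion in severe COPD) pulls off-diagonal entries
down.  The scalar summary is the mean over the N(N-1)/2 strictly
upper-triangular pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateWaveformError
from .waveforms import WaveformSet

__all__ = ["NCCMap", "ncc", "build_ncc_map", "render_ncc_map"]

logger = logging.getLogger(__name__)


@dataclass
class NCCMap:
    """Pairwise NCC matrix over diaphragm positions."""

    R: np.ndarray  # (N, N) symmetric, unit diagonal
    positions: np.ndarray  # y labels of the retained (non-degenerate) columns
    mean_ncc: float  # mean of the strict upper triangle
    excluded_positions: np.ndarray  # degenerate columns dropped, if any

    @property
    def n(self) -> int:
        return self.R.shape[0]

    def write_csv(self, path) -> None:
        import json
        from pathlib import Path

        import pandas as pd

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        labels = [f"y{int(y)}" for y in self.positions]
        pd.DataFrame(self.R, index=labels, columns=labels).to_csv(
            path, float_format="%.8g"
        )
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "mean_ncc": float(self.mean_ncc),
                    "n_positions": int(self.n),
                    "excluded_positions": [int(y) for y in self.excluded_positions],
                },
                fh,
                indent=1,
            )


def ncc(w_i: np.ndarray, w_j: np.ndarray) -> float:
    """Zero-lag NCC of two equal-length centered waveforms, in [-1, 1].

    Raises
    ------
    DegenerateWaveformError
        If either waveform has zero energy (constant input), which leaves
        the denominator undefined.
    """
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    if w_i.shape != w_j.shape or w_i.ndim != 1 or w_i.size < 2:
        raise ValueError("ncc expects two 1-D waveforms of equal length >= 2")
    e_i = float(w_i @ w_i)
    e_j = float(w_j @ w_j)
    if e_i == 0.0 or e_j == 0.0:
        raise DegenerateWaveformError("degenerate waveform: zero energy")
    return float((w_i @ w_j) / np.sqrt(e_i * e_j))


def build_ncc_map(waves: WaveformSet) -> NCCMap:
    """Assemble the full NCC matrix and its upper-triangle mean.

    Degenerate (constant) position waveforms are excluded with a warning —
    a frozen column reflects a segmentation problem, not zero similarity —
    and N shrinks accordingly.
    """
    Z = np.asarray(waves.z_centered, dtype=float)  # (N, M)
    energy = np.einsum("ij,ij->i", Z, Z)
    keep = energy > 0.0
    excluded = waves.positions[~keep]
    if excluded.size:
        logger.warning(
            "%s: excluding %d degenerate (constant) waveform(s) at y=%s",
            waves.subject_id,
            excluded.size,
            excluded[:10].tolist(),
        )
    Z = Z[keep]
    if Z.shape[0] < 2:
        raise DegenerateWaveformError(
            "fewer than 2 non-degenerate waveforms; NCC map undefined"
        )
    norm = np.sqrt(energy[keep])
    R = (Z @ Z.T) / np.outer(norm, norm)
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    iu = np.triu_indices(R.shape[0], k=1)
    return NCCMap(
        R=R,
        positions=waves.positions[keep],
        mean_ncc=float(R[iu].mean()),
        excluded_positions=excluded,
    )


def render_ncc_map(ncc_map: NCCMap, path, dpi: int = 150) -> None:
    """Render the upper triangle of the NCC map as a heat map image.

    The color scale is fixed to [0, 1] so maps are comparable across
    subjects; negative entries are clamped in the image (and logged) but
    kept verbatim in the CSV output.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_neg = int((ncc_map.R[np.triu_indices(ncc_map.n, k=1)] < 0).sum())
    if n_neg:
        logger.warning("NCC map has %d negative pair(s); clamped to 0 in image", n_neg)
    shown = np.where(np.tril(np.ones_like(ncc_map.R, dtype=bool), k=-1), np.nan, ncc_map.R)
    fig, ax = plt.subplots(figsize=(5.2, 4.4))
    im = ax.imshow(shown, vmin=0.0, vmax=1.0, cmap="jet_r", interpolation="nearest")
    ticks = np.linspace(0, ncc_map.n - 1, min(6, ncc_map.n)).astype(int)
    ax.set_xticks(ticks, [str(int(ncc_map.positions[t])) for t in ticks])
    ax.set_yticks(ticks, [str(int(ncc_map.positions[t])) for t in ticks])
    ax.set_xlabel("position j (Y, px)")
    ax.set_ylabel("position i (Y, px)")
    ax.set_title(f"NCC map (mean {ncc_map.mean_ncc:.2f})")
    fig.colorbar(im, ax=ax, label="NCC")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
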