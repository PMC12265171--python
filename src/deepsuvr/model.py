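"""The correction-factor network.

A small 3D convolutional encoder (kernel 4, stride 4, instance norm,
leaky rectification), flattened and concatenated with a length-5 tracer
one-hot, followed by two fully connected blocks (dropout 0.5, affine,
batch norm, tanh) and an affine head squashed through ``2 * logistic``
so the correction factor CF always lies in [0, 2] by construction.

The number of convolutional blocks is derived from the grid: stride-4
blocks are stacked while every axis still spans at least one full
kernel, capped at four.  On the desk-scale 32x40x32 grid that gives two
blocks; the full 91x109x91 template grid gets the deeper stack.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .io import TRACERS, ScanRecord, VolumeGrid
from .quantify import MaskPair, TransformTable, apply_correction, compute_suvr, suvr_to_centiloid


@dataclasses.dataclass(frozen=True)
class CorrectionFactor:
    cf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cf <= 2.0):
            raise ValueError(f"correction factor outside [0,2]: {self.cf}")


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters; conv depth is derived from the grid."""

    channels: tuple[int, ...] = (16, 32, 64, 128)
    fc_widths: tuple[int, int] = (256, 64)
    dropout_rate: float = 0.5
    leaky_slope: float = 0.01

    def n_conv_blocks(self, grid: VolumeGrid) -> int:
        k = 0
        spatial = list(grid.shape)
        while k < len(self.channels) and min(s // 4 for s in spatial) >= 1:
            spatial = [s // 4 for s in spatial]
            k += 1
        if k == 0:
            raise ValueError(f"grid {grid.shape} too small for a stride-4 encoder")
        return k

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class CorrectionNet:
    """CF regressor: SUVR-normalised volume + tracer one-hot -> CF in [0,2]."""

    def __init__(self, grid: VolumeGrid, spec: NetworkSpec | None = None, seed: int = 0):
        self.grid = grid
        self.spec = spec or NetworkSpec()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 10_000)

        n_blocks = self.spec.n_conv_blocks(grid)
        self.conv_layers: list[nn.Layer] = []
        c_in = 1
        spatial = grid.shape
        for b in range(n_blocks):
            c_out = self.spec.channels[b]
            conv = nn.Conv3dStride4(c_in, c_out, rng)
            if b == 0:
                conv.skip_input_grad = True
            self.conv_layers += [conv, nn.InstanceNorm3d(), nn.LeakyReLU(self.spec.leaky_slope)]
            spatial = nn.Conv3dStride4.out_shape(spatial)
            c_in = c_out
        assert min(spatial) >= 1
        self.flat_dim = c_in * int(np.prod(spatial))

        d_in = self.flat_dim + len(TRACERS)
        self.fc_layers: list[nn.Layer] = []
        for width in self.spec.fc_widths:
            self.fc_layers += [
                nn.Dropout(self.spec.dropout_rate, self._dropout_rng),
                nn.Linear(d_in, width, rng),
                nn.BatchNorm1d(width),
                nn.Tanh(),
            ]
            d_in = width
        self.head = nn.Linear(d_in, 1, rng)
        self.squash = nn.DoubledSigmoid()

    # ------------------------------------------------------------------ #

    def parameters(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for layer in [*self.conv_layers, *self.fc_layers, self.head]:
            ps.extend(layer.params())
        return ps

    def forward(self, volumes: np.ndarray, tracer_onehots: np.ndarray, train: bool) -> np.ndarray:
        """Batched forward pass; volumes (N, X, Y, Z), one-hots (N, 5)."""
        if volumes.shape[1:] != self.grid.shape:
            raise ValueError(f"volume shape {volumes.shape[1:]} does not match grid {self.grid.shape}")
        x = np.ascontiguousarray(volumes[:, None], dtype=nn.DTYPE)
        tracer_onehots = tracer_onehots.astype(nn.DTYPE, copy=False)
        for layer in self.conv_layers:
            x = layer.forward(x, train)
        self._conv_out_shape = x.shape
        x = x.reshape(x.shape[0], -1)
        x = np.concatenate([x, tracer_onehots], axis=1)
        for layer in self.fc_layers:
            x = layer.forward(x, train)
        x = self.head.forward(x, train)
        cf = self.squash.forward(x, train)
        return cf[:, 0]

    def backward(self, dcf: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dCF per sample."""
        g = self.squash.backward(np.asarray(dcf, dtype=nn.DTYPE)[:, None])
        g = self.head.backward(g)
        for layer in reversed(self.fc_layers):
            g = layer.backward(g)
        g = g[:, : self.flat_dim].reshape(self._conv_out_shape)
        for layer in reversed(self.conv_layers):
            g = layer.backward(g)

    # ------------------------------------------------------------------ #

    def predict_cf(self, volume: np.ndarray, tracer: str) -> CorrectionFactor:
        """Single-image inference in evaluation mode."""
        if tracer not in TRACERS:
            raise ValueError(f"unknown tracer {tracer!r}")
        cf = self.forward(volume[None], tracer_onehot(tracer)[None], train=False)
        return CorrectionFactor(float(cf[0]))

    def state_dict(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.parameters()],
            "running": [
                (l.running_mean.copy(), l.running_var.copy())
                for l in self.fc_layers
                if isinstance(l, nn.BatchNorm1d)
            ],
        }

    def load_state_dict(self, state: dict) -> None:
        for p, v in zip(self.parameters(), state["params"]):
            p.value = v.copy()
        bns = [l for l in self.fc_layers if isinstance(l, nn.BatchNorm1d)]
        for bn, (mean, var) in zip(bns, state["running"]):
            bn.running_mean = mean.copy()
            bn.running_var = var.copy()

    def save(self, path: str | Path) -> None:
        """Checkpoint as .npz with a JSON sidecar describing the config."""
        path = Path(path)
        state = self.state_dict()
        arrays = {f"param_{i}": v for i, v in enumerate(state["params"])}
        for i, (mean, var) in enumerate(state["running"]):
            arrays[f"bn_mean_{i}"] = mean
            arrays[f"bn_var_{i}"] = var
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "grid": {"shape": self.grid.shape, "voxel_size_mm": self.grid.voxel_size_mm,
                     "left_right_axis": self.grid.left_right_axis},
            "spec": self.spec.to_dict(),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        grid = VolumeGrid(
            shape=tuple(sidecar["grid"]["shape"]),
            voxel_size_mm=sidecar["grid"]["voxel_size_mm"],
            left_right_axis=sidecar["grid"]["left_right_axis"],
        )
        spec_d = sidecar["spec"]
        spec = NetworkSpec(
            channels=tuple(spec_d["channels"]),
            fc_widths=tuple(spec_d["fc_widths"]),
            dropout_rate=spec_d["dropout_rate"],
            leaky_slope=spec_d["leaky_slope"],
        )
        net = cls(grid, spec, seed=sidecar["seed"])
        data = np.load(path.with_suffix(".npz"))
        n_params = len(net.parameters())
        state = {
            "params": [data[f"param_{i}"] for i in range(n_params)],
            "running": [
                (data[f"bn_mean_{i}"], data[f"bn_var_{i}"])
                for i in range(len(spec.fc_widths))
            ],
        }
        net.load_state_dict(state)
        return net


def tracer_onehot(tracer: str) -> np.ndarray:
    vec = np.zeros(len(TRACERS))
    vec[TRACERS.index(tracer)] = 1.0
    return vec


def correct_scan(
    scan: ScanRecord,
    masks: MaskPair,
    transforms: TransformTable,
    model: CorrectionNet,
) -> tuple[float, float, float, float]:
    """Quantify one scan: (standard SUVR, CF, corrected SUVR, corrected CL)."""
    standard_suvr = compute_suvr(scan.volume, masks)
    cf = model.predict_cf(scan.volume, scan.tracer).cf
    corrected_suvr = apply_correction(standard_suvr, cf)
    corrected_cl = suvr_to_centiloid(corrected_suvr, scan.tracer, transforms)
    return standard_suvr, cf, corrected_suvr, corrected_cl
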