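"""Multi-shell PGSE acquisition protocols.

A protocol is the coordinate system for all signal math in this package:
a set of b-shells (diffusion weighting, number of directions) plus the
pulsed-gradient timings (gradient duration ``delta_small`` and gradient
separation ``delta_big``).

Unit conventions (internal to the package):

* b-value: ms/um^2  (= s/mm^2 divided by 1000), so diffusivities are O(1)
* times: ms
* diffusivity: um^2/ms
* radius: um

Readers accept b-values in s/mm^2 (the convention of bval files) and
convert on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["Shell", "AcquisitionProtocol", "connectom_protocol"]

#: b-values below this (ms/um^2) are treated as b=0 for shell grouping.
B0_THRESHOLD = 0.05


@dataclass(frozen=True)
class Shell:
    """One b-shell: nominal b-value (ms/um^2) and direction count."""

    b_value: float
    n_directions: int

    def __post_init__(self) -> None:
        if self.b_value < 0:
            raise ValueError(f"negative b-value: {self.b_value}")
        if self.n_directions < 1:
            raise ValueError("shell needs at least one direction")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-shell PGSE protocol with gradient timings.

    Parameters
    ----------
    shells
        Shells in ascending b order. At least one must be b=0 (used for
        normalization of spherical-mean signals).
    delta_small
        Gradient pulse duration delta, ms.
    delta_big
        Gradient pulse separation Delta, ms. Must exceed ``delta_small``.
    directions
        Optional per-shell unit direction vectors, one ``(n_i, 3)`` array
        per shell (b=0 shells may carry arbitrary placeholder vectors).
    """

    shells: tuple[Shell, ...]
    delta_small: float
    delta_big: float
    directions: tuple[np.ndarray, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.shells:
            raise ValueError("protocol has no shells")
        if not self.delta_small < self.delta_big:
            raise ValueError(
                f"require delta < Delta, got delta={self.delta_small}, "
                f"Delta={self.delta_big}"
            )
        if self.delta_small <= 0:
            raise ValueError("delta must be positive")
        if not any(s.b_value <= B0_THRESHOLD for s in self.shells):
            raise ValueError("protocol needs a b=0 shell for normalization")
        if self.directions is not None:
            if len(self.directions) != len(self.shells):
                raise ValueError("one direction block per shell required")
            for sh, dirs in zip(self.shells, self.directions):
                dirs = np.asarray(dirs, float)
                if dirs.shape != (sh.n_directions, 3):
                    raise ValueError(
                        f"shell b={sh.b_value}: direction block shape "
                        f"{dirs.shape} != ({sh.n_directions}, 3)"
                    )
                if sh.b_value > B0_THRESHOLD:
                    norms = np.linalg.norm(dirs, axis=1)
                    if not np.allclose(norms, 1.0, atol=1e-6):
                        raise ValueError("direction vectors must be unit norm")

    # -- derived views ---------------------------------------------------

    @property
    def b_values(self) -> np.ndarray:
        """Nominal b per shell (ms/um^2)."""
        return np.array([s.b_value for s in self.shells])

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    @property
    def nonzero_shells(self) -> tuple[Shell, ...]:
        return tuple(s for s in self.shells if s.b_value > B0_THRESHOLD)

    @property
    def b0_index(self) -> int:
        """Index of the (first) b=0 shell."""
        for i, s in enumerate(self.shells):
            if s.b_value <= B0_THRESHOLD:
                return i
        raise AssertionError("unreachable: validated in __post_init__")

    @property
    def shell_assignment(self) -> np.ndarray:
        """Shell index for each acquired volume, in shell order."""
        return np.repeat(
            np.arange(self.n_shells), [s.n_directions for s in self.shells]
        )

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_bval_bvec(
        cls,
        bval_path,
        bvec_path,
        delta_small: float,
        delta_big: float,
        b_tol: float = 0.05,
    ) -> "AcquisitionProtocol":
        """Build a protocol from FSL-style bval/bvec text files.

        bval holds one row of b-values in s/mm^2; bvec holds three rows of
        direction components. Volumes are grouped into shells by rounding
        b/1000 to within ``b_tol`` ms/um^2.
        """
        bvals = np.loadtxt(bval_path, ndmin=1) / 1000.0
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvec shape {bvecs.shape} incompatible with {bvals.size} b-values"
            )
        # cluster b-values into shells
        order = np.argsort(bvals)
        shell_b: list[float] = []
        labels = np.empty(bvals.size, int)
        for i in order:
            b = bvals[i]
            if shell_b and abs(b - shell_b[-1]) <= b_tol:
                labels[i] = len(shell_b) - 1
            else:
                shell_b.append(b)
                labels[i] = len(shell_b) - 1
        shells, dir_blocks = [], []
        for j, b in enumerate(shell_b):
            mask = labels == j
            b_nom = 0.0 if b <= B0_THRESHOLD else float(np.mean(bvals[mask]))
            shells.append(Shell(b_nom, int(mask.sum())))
            vecs = bvecs[mask]
            if b_nom > B0_THRESHOLD:
                norms = np.linalg.norm(vecs, axis=1, keepdims=True)
                vecs = vecs / np.where(norms == 0, 1.0, norms)
            dir_blocks.append(vecs)
        return cls(tuple(shells), delta_small, delta_big, tuple(dir_blocks))

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionProtocol":
        """Load shells and timings from a YAML sidecar.

        Expected keys: ``delta_small_ms``, ``delta_big_ms`` and ``shells``,
        a list of ``{b_s_mm2: ..., n_directions: ...}`` entries.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        shells = tuple(
            Shell(float(s["b_s_mm2"]) / 1000.0, int(s["n_directions"]))
            for s in cfg["shells"]
        )
        return cls(shells, float(cfg["delta_small_ms"]), float(cfg["delta_big_ms"]))

    def to_yaml(self, path) -> None:
        cfg = {
            "delta_small_ms": float(self.delta_small),
            "delta_big_ms": float(self.delta_big),
            "shells": [
                {"b_s_mm2": float(s.b_value * 1000.0), "n_directions": s.n_directions}
                for s in self.shells
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def connectom_protocol() -> AcquisitionProtocol:
    """The ultra-strong-gradient study protocol.

    delta=7 ms, Delta=23.3 ms; b = 0 (14 vols), 500 and 1200 s/mm^2 at 30
    directions, 2400, 4000 and 6000 s/mm^2 at 60 directions.
    """
    shells = (
        Shell(0.0, 14),
        Shell(0.5, 30),
        Shell(1.2, 30),
        Shell(2.4, 60),
        Shell(4.0, 60),
        Shell(6.0, 60),
    )
    return AcquisitionProtocol(shells, delta_small=7.0, delta_big=23.3)
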