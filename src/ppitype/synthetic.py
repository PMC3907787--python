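"""Synthetic fixtures: toy two-chain complexes with controlled geometry and
charges, labelled complex datasets, and labelled Gaussian feature data.

The toy complex places each chain's atoms on a square grid in a plane, the
two planes separated by a configurable gap, so expected contact counts at
any cutoff follow from the grid geometry in closed form.  Residue names
cycle through the 20 standard amino acids and every atom is named CA, so
typing always succeeds; charges are unit-magnitude for hand-checkable
energies.  The two-population generator emulates the qualitative contrast
between obligate complexes (larger interfaces with complementary facing
charges) and non-obligate ones (smaller interfaces, weaker charge
complementarity); it makes no claim of physical realism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .structure import (Atom, Complex, STANDARD_RESIDUES, assign_types,
                        default_table, write_pqr)


@dataclass
class ToyComplexSpec:
    """Geometry/charge plan for one grid-on-grid toy complex.

    ``charge_plan``: 'alternating' (+1/-1 checkerboard on both chains),
    'complementary' (+1 everywhere on the ligand, -1 on the receptor),
    'random' (+/-1 i.i.d.), or 'fixed' (all ``charge_value``).
    ``far_layer_gap``/``far_layer_plan``: optional second receptor layer at
    this distance from the ligand plane, with its own charge plan, used to
    place class signal at long range only.
    """

    n_side: int = 3
    spacing: float = 10.0
    gap: float = 6.0
    jitter: float = 0.0
    charge_plan: str = "alternating"
    charge_value: float = 1.0
    ligand_plan: str | None = None
    receptor_plan: str | None = None
    far_layer_gap: float | None = None
    far_layer_plan: str = "random"
    seed: int = 0


def _plan_charges(plan: str, n: int, sign: float, value: float,
                  rng: np.random.Generator) -> np.ndarray:
    if plan == "alternating":
        return value * np.array([1.0 if i % 2 == 0 else -1.0
                                 for i in range(n)])
    if plan == "complementary":
        return np.full(n, sign * value)
    if plan == "random":
        return value * rng.choice([-1.0, 1.0], size=n)
    if plan == "fixed":
        return np.full(n, value)
    raise ValueError(f"unknown charge plan: {plan!r}")


def make_toy_complex(spec: ToyComplexSpec, path: str | Path | None = None,
                     *, label: str | None = None,
                     name: str = "toy") -> Complex:
    """Build (and optionally write as PQR) one two-chain grid complex.

    Chain A sits at z = 0, chain B at z = gap, nodes aligned, so at zero
    jitter the cross-chain distance between opposing nodes is exactly the
    gap and between laterally adjacent nodes sqrt(spacing² + gap²).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_side ** 2

    def grid(z: float) -> np.ndarray:
        xy = np.array([(i * spec.spacing, j * spec.spacing)
                       for i in range(spec.n_side)
                       for j in range(spec.n_side)], dtype=float)
        xyz = np.column_stack([xy, np.full(len(xy), z)])
        if spec.jitter > 0:
            xyz = xyz + rng.normal(0, spec.jitter, xyz.shape)
        return xyz

    a_xyz = grid(0.0)
    b_xyz = grid(spec.gap)
    qa = _plan_charges(spec.ligand_plan or spec.charge_plan, n, +1.0,
                       spec.charge_value, rng)
    qb = _plan_charges(spec.receptor_plan or spec.charge_plan, n, -1.0,
                       spec.charge_value, rng)
    coords = [("A", a_xyz, qa), ("B", b_xyz, qb)]
    if spec.far_layer_gap is not None:
        far_xyz = grid(spec.far_layer_gap)
        qf = _plan_charges(spec.far_layer_plan, n, -1.0, spec.charge_value,
                           rng)
        coords.append(("B", far_xyz, qf))

    atoms: list[Atom] = []
    serial = 1
    resseq = 1
    for chain, xyz, charges in coords:
        for pos, q in zip(xyz, charges):
            res = STANDARD_RESIDUES[(resseq - 1) % len(STANDARD_RESIDUES)]
            atoms.append(Atom(serial=serial, name="CA", residue_name=res,
                              chain_id=chain, residue_seq=resseq,
                              coords=pos, charge=float(q), radius=1.7))
            serial += 1
            resseq += 1
    cplx = Complex(id=name, atoms=atoms, ligand_chains=frozenset("A"),
                   receptor_chains=frozenset("B"), label=label)
    assign_types(cplx, default_table())
    if path is not None:
        write_pqr(cplx, path)
    return cplx


def expected_grid_contacts(spec: ToyComplexSpec, cutoff: float) -> int:
    """Closed-form contact count for a jitter-free aligned grid pair."""
    if spec.jitter > 0:
        raise ValueError("closed form requires zero jitter")
    n = spec.n_side
    count = 0
    for i1 in range(n):
        for j1 in range(n):
            for i2 in range(n):
                for j2 in range(n):
                    dx = (i1 - i2) * spec.spacing
                    dy = (j1 - j2) * spec.spacing
                    d = np.sqrt(dx * dx + dy * dy + spec.gap ** 2)
                    if d < cutoff:
                        count += 1
    return count


#: study-condition defaults for the two synthetic populations: the obligate
#: population has the larger interface (6x6 grid) with fully complementary
#: facing charges; the non-obligate one is smaller (4x4) with random signs.
OBLIGATE_SPEC = ToyComplexSpec(n_side=6, spacing=5.0, gap=4.5, jitter=0.3,
                               charge_plan="complementary")
NONOBLIGATE_SPEC = ToyComplexSpec(n_side=4, spacing=5.0, gap=5.5, jitter=0.3,
                                  charge_plan="random")


def make_labeled_dataset(out_dir: str | Path, n_per_class: int = 40,
                         obligate_spec: ToyComplexSpec = OBLIGATE_SPEC,
                         nonobligate_spec: ToyComplexSpec = NONOBLIGATE_SPEC,
                         seed: int = 0) -> Path:
    """Write 2·n toy complexes + manifest CSV; returns the manifest path.

    Each complex gets a fresh sub-seed so jitter and random charges differ
    across complexes while the whole dataset is reproducible from ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for label, spec in (("obligate", obligate_spec),
                        ("non-obligate", nonobligate_spec)):
        for i in range(n_per_class):
            sub = replace(spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
            fname = f"{label.replace('-', '')}_{i:03d}.pqr"
            make_toy_complex(sub, out_dir / fname, label=label,
                             name=fname.removesuffix(".pqr"))
            rows.append((fname, "A:B", label))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "partition", "label"])
        writer.writerows(rows)
    return manifest


def make_longrange_dataset(out_dir: str | Path, n_per_class: int = 30,
                           seed: int = 0) -> Path:
    """Dataset whose class signal lives only in 8-10 Å contacts.

    Both classes share the same near geometry (receptor layer at 4.5 Å,
    random charges), so short cutoffs see pure noise.  A second receptor
    layer at 8.5 Å carries the signal: complementary to the ligand's +1
    charges in the obligate class, random in the non-obligate class.  A
    cutoff sweep should therefore peak at >= 8 Å.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = ToyComplexSpec(n_side=5, spacing=6.0, gap=4.5, jitter=0.2,
                          charge_plan="fixed", charge_value=1.0,
                          ligand_plan="fixed", receptor_plan="random",
                          far_layer_gap=8.5)
    rows = []
    for label, far_plan in (("obligate", "complementary"),
                            ("non-obligate", "random")):
        for i in range(n_per_class):
            spec = replace(base, far_layer_plan=far_plan,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
            fname = f"lr_{label.replace('-', '')}_{i:03d}.pqr"
            make_toy_complex(spec, out_dir / fname, label=label,
                             name=fname.removesuffix(".pqr"))
            rows.append((fname, "A:B", label))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "partition", "label"])
        writer.writerows(rows)
    return manifest


@dataclass
class GaussianDatasetSpec:
    """Two labelled Gaussian clouds with known moments."""

    n_per_class: int = 100
    dim: int = 2
    mean0: np.ndarray | None = None
    mean1: np.ndarray | None = None
    cov0: np.ndarray | None = None
    cov1: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        eye = np.eye(self.dim)
        self.mean0 = (np.zeros(self.dim) if self.mean0 is None
                      else np.asarray(self.mean0, float))
        self.mean1 = (np.zeros(self.dim) if self.mean1 is None
                      else np.asarray(self.mean1, float))
        self.cov0 = eye if self.cov0 is None else np.asarray(self.cov0, float)
        self.cov1 = eye if self.cov1 is None else np.asarray(self.cov1, float)
        for S in (self.cov0, self.cov1):
            if not np.allclose(S, S.T) or np.linalg.eigvalsh(S)[0] <= 0:
                raise ValueError("covariances must be symmetric PD")


def make_gaussian_dataset(spec: GaussianDatasetSpec
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Sample (X, y) from the two specified Gaussians, y in {0, 1}."""
    rng = np.random.default_rng(spec.seed)
    X0 = rng.multivariate_normal(spec.mean0, spec.cov0, spec.n_per_class)
    X1 = rng.multivariate_normal(spec.mean1, spec.cov1, spec.n_per_class)
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(spec.n_per_class, int), np.ones(spec.n_per_class, int)]
    return X, y
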