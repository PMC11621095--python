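"""Synthetic two-group resting-state cohort with a modular functional architecture.

The generator emulates a case-control resting-state fMRI study at the
region-of-interest level: 30 patients and 24 controls, TR = 1 s, 400
volumes, 90 atlas regions. Each region's series is a linear mixture of
band-limited (0.01-0.08 Hz) unit-variance Gaussian latent signals:

    x_i = c_g * m_pri(i) + 0.643 c_g * m_sec(i) + b * g
          + hub/planted/clique pair signals + noise_sd * eps_i

* ``m_k`` - one latent signal per functional module (6 modules of 15
  regions; every region also loads on a secondary module, giving the
  overlapping community structure real functional parcellations show);
* ``g`` - a global signal shared by all regions;
* hub pair signals - a deterministic set of strong inter-module region
  pairs (a backbone of long-range hub connections) that keeps the
  thresholded networks integrated at low edge densities, as strong
  long-range connections do in empirical connectomes;
* planted pair signals and a planted nodal deficit - the injectable
  patient effect (see ``CohortSpec``).

Because every region is a linear mixture of independent unit-variance
latents, the implied covariance is positive semi-definite by construction;
the ``CohortSpec`` validator rejects coupling sets whose systematic part
would need negative residual variance.

The patient group uses a lower within-module coupling, which lowers the
signal-to-noise ratio of its correlation structure and thereby the
clustering coefficient and local efficiency of its thresholded networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RoiTimeSeries, bandpass_array
from . import atlas

DEFAULT_BAND_HZ = (0.01, 0.08)


@dataclass(frozen=True)
class PlantedEdge:
    """A region pair given an extra shared signal with group-specific
    amplitude; ``amp_patient > amp_control`` plants a connection that is
    stronger in patients, and vice versa."""

    i: int
    j: int
    amp_patient: float
    amp_control: float


def _triangle_chain(triples: list[tuple[int, int, int]]) -> list[tuple[int, int]]:
    edges = []
    for a, b, c in triples:
        edges += [(a, b), (a, c), (b, c)]
    return edges


def _default_planted_edges() -> list[PlantedEdge]:
    # two connected 15-edge chains of triangles (triangles keep each
    # affected node's neighbourhood interconnected, so the extra pair
    # signals alter connectivity without wrecking local efficiency at
    # those nodes): an occipital/precuneus/fusiform cluster strengthened
    # in patients, an inferior-frontal/temporal cluster weakened
    inc = _triangle_chain(
        [(48, 52, 66), (66, 54, 49), (49, 53, 67), (67, 55, 50), (50, 42, 44)]
    )
    dec = _triangle_chain(
        [(10, 14, 12), (12, 84, 11), (11, 15, 13), (13, 85, 89), (89, 88, 80)]
    )
    return [PlantedEdge(i, j, 1.2, 0.0) for i, j in inc] + [
        PlantedEdge(i, j, 0.0, 1.2) for i, j in dec
    ]


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Couplings are standard deviations of unit-variance latent components,
    so the expected correlation between two regions of the same module is
    c^2 / (c^2 + ... + noise_sd^2). Defaults give within-module
    correlations of ~0.31 (controls) / ~0.26 (patients) and produce
    small-world binary networks across the whole sparsity sweep.
    """

    n_patients: int = 30
    n_controls: int = 24
    n_regions: int = 90
    n_volumes: int = 400
    tr_seconds: float = 1.0
    n_modules: int = 6
    module_assignment: np.ndarray | None = None  # primary module per region
    within_module_coupling: dict = field(
        default_factory=lambda: {"patient": 0.56, "control": 0.70}
    )
    secondary_coupling_ratio: float = 0.643
    between_module_coupling: float = 0.20
    # deterministic per-region spread of the primary coupling (fractional
    # half-range); heterogeneous coupling concentrates the strongest
    # within-module correlations on a connected core of each module, as
    # the graded region-to-network affiliation of real parcellations does
    coupling_heterogeneity: float = 0.0
    # strong long-range hub connections: inter-module region pairs that
    # share a dedicated latent signal and keep the thresholded networks
    # integrated at low edge densities
    hub_coupling: float = 1.316
    n_hub_pairs_per_link: int = 3
    # None = auto: the default planted effects for 90-region cohorts, no
    # planted effects otherwise
    planted_edges: list[PlantedEdge] | None = None
    planted_node: int | None = -1  # -1 = auto (right amygdala at 90 regions)
    planted_node_retention: float = 0.25
    # a tightly coupled sub-community containing the planted node (default:
    # the bilateral hippocampus/parahippocampus/amygdala block), present in
    # both groups; the patient-side decoupling of the planted node then
    # removes a genuinely cliquish neighbourhood
    clique_regions: tuple[int, ...] | None = None  # None = auto
    clique_coupling: float = 0.8
    noise_sd: float = 1.0
    motion_scale: float = 0.2
    qc_violator_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed 10")
        if self.n_regions < 2 or self.n_modules < 1:
            raise ValueError("need at least 2 regions and 1 module")
        if self.module_assignment is None:
            self.module_assignment = (
                np.arange(self.n_regions) * self.n_modules // self.n_regions
            )
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.shape != (self.n_regions,):
            raise ValueError("module_assignment must have one entry per region")
        bad = []
        for grp, c in self.within_module_coupling.items():
            if not 0 <= c < 1:
                bad.append(f"within_module_coupling[{grp}]={c}")
        if not 0 <= self.between_module_coupling < 1:
            bad.append(f"between_module_coupling={self.between_module_coupling}")
        for grp, c in self.within_module_coupling.items():
            sys_var = (
                c**2 * (1 + self.secondary_coupling_ratio**2)
                + self.between_module_coupling**2
            )
            if self.noise_sd == 0 and sys_var == 0:
                bad.append(f"all couplings zero for group {grp} with noise_sd=0")
        if bad:
            raise ValueError(
                "coupling parameterization does not yield a valid positive "
                "semi-definite covariance: " + ", ".join(bad)
            )
        if self.planted_edges is None:
            self.planted_edges = (
                _default_planted_edges() if self.n_regions == atlas.N_REGIONS else []
            )
        if self.planted_node == -1:
            self.planted_node = (
                atlas.RIGHT_AMYGDALA if self.n_regions == atlas.N_REGIONS else None
            )
        if self.clique_regions is None:
            self.clique_regions = (
                (36, 37, 38, 39, 40, 41)
                if self.n_regions == atlas.N_REGIONS
                else ()
            )
        self.clique_regions = tuple(self.clique_regions)
        if any(not 0 <= i < self.n_regions for i in self.clique_regions):
            raise ValueError("clique_regions reference invalid region indices")
        if not 0 <= self.clique_coupling < 1.5:
            raise ValueError(f"clique_coupling={self.clique_coupling} out of range")
        for e in self.planted_edges:
            if not (0 <= e.i < self.n_regions and 0 <= e.j < self.n_regions) or e.i == e.j:
                raise ValueError(f"planted edge ({e.i},{e.j}) references invalid regions")
        if self.planted_node is not None and not 0 <= self.planted_node < self.n_regions:
            raise ValueError(f"planted_node {self.planted_node} out of range")
        if not 0 <= self.planted_node_retention <= 1:
            raise ValueError("planted_node_retention must be in [0,1]")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def coupling_gains(self) -> np.ndarray:
        """Fixed per-region multipliers of the primary coupling, spread
        quasi-uniformly over [1 - h, 1 + h] by a lag-37 stride so adjacent
        regions of a module differ."""
        h = self.coupling_heterogeneity
        if h == 0:
            return np.ones(self.n_regions)
        i = np.arange(self.n_regions)
        frac = (i * 37 % self.n_regions) / max(self.n_regions - 1, 1)
        return 1.0 + h * (2.0 * frac - 1.0)

    def secondary_assignment(self) -> np.ndarray:
        """Deterministic secondary-module membership cycling over the other
        modules, so regions load on two overlapping communities and
        between-module correlation gradients arise from shared factors."""
        pri = self.module_assignment
        K = self.n_modules
        if K == 1:
            return pri.copy()
        return np.array(
            [(pri[i] + 1 + (i % (K - 1))) % K for i in range(self.n_regions)]
        )

    def _reserved_regions(self) -> set[int]:
        """Regions carrying planted effects or clique membership; hub
        structure avoids them so the injected group effects are not
        confounded."""
        reserved = {self.planted_node} if self.planted_node is not None else set()
        reserved.update(self.clique_regions)
        for e in self.planted_edges:
            reserved.update((e.i, e.j))
        return reserved

    def hub_pairs(self) -> list[tuple[int, int]]:
        """Deterministic inter-module hub connections: a ring over the
        modules plus skip-one and skip-two chords, ``n_hub_pairs_per_link``
        region pairs each. Regions carrying planted effects or belonging
        to the tight clique are skipped so the injected group effects are
        not confounded with hub structure."""
        K = self.n_modules
        if K < 2:
            return []
        links = [(k, (k + 1) % K) for k in range(K)]
        if K > 3:
            links += [(k, (k + 2) % K) for k in range(K)]
        if K > 5:
            links += [(k, k + 3) for k in range(K // 2)]
        reserved = self._reserved_regions()
        members = {
            k: [
                int(i)
                for i in np.flatnonzero(self.module_assignment == k)
                if i not in reserved
            ]
            for k in range(K)
        }
        counters = dict.fromkeys(range(K), 0)
        pairs: list[tuple[int, int]] = []
        for ka, kb in links:
            for _ in range(self.n_hub_pairs_per_link):
                ma, mb = members[ka], members[kb]
                if not ma or not mb:
                    continue
                i = ma[counters[ka] % len(ma)]
                j = mb[counters[kb] % len(mb)]
                counters[ka] += 1
                counters[kb] += 1
                if i != j:
                    pairs.append((i, j))
        return pairs


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: int  # 0/1
    education: float
    timeseries: RoiTimeSeries
    motion: np.ndarray  # (n_volumes, 6)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.motion.shape != (self.timeseries.n_volumes, 6):
            raise ValueError("motion must have one 6-vector row per volume")


def _band_unit(rng: np.random.Generator, n_volumes: int, n_signals: int,
               tr: float) -> np.ndarray:
    """Band-limited unit-variance latent signals, one per column."""
    x = bandpass_array(
        rng.standard_normal((n_volumes, n_signals)), tr, *DEFAULT_BAND_HZ
    )
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_rng(spec: CohortSpec, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, subject_index, stream])
    )


def generate_timeseries(spec: CohortSpec, subject_index: int, group: str) -> np.ndarray:
    """One subject's (n_volumes, n_regions) series under the latent model."""
    rng = _subject_rng(spec, subject_index, 0)
    T, N, K = spec.n_volumes, spec.n_regions, spec.n_modules
    tr = spec.tr_seconds
    pri = spec.module_assignment
    sec = spec.secondary_assignment()
    c1 = spec.within_module_coupling[group]
    c2 = spec.secondary_coupling_ratio * c1
    b = spec.between_module_coupling

    m = _band_unit(rng, T, K, tr)
    g = _band_unit(rng, T, 1, tr)[:, 0]
    eps = _band_unit(rng, T, N, tr)

    u = spec.coupling_gains()
    x = (
        (c1 * u) * m[:, pri]
        + c2 * m[:, sec]
        + b * g[:, None]
        + spec.noise_sd * eps
    )

    # tight sub-community shared by both groups
    cq = spec.clique_coupling
    q = _band_unit(rng, T, 1, tr)[:, 0]
    if spec.clique_regions:
        x[:, list(spec.clique_regions)] += cq * q[:, None]

    # planted nodal deficit: in patients the planted node's systematic
    # content (module, secondary module and clique signals) is largely
    # replaced by an equal-variance private signal, decoupling it from
    # its neighbourhood
    if (
        group == "patient"
        and spec.planted_node is not None
        and spec.planted_node_retention < 1
    ):
        alpha = spec.planted_node_retention
        i = spec.planted_node
        priv = _band_unit(rng, T, 1, tr)[:, 0]
        c1_i = c1 * u[i]
        sys_i = c1_i * m[:, pri[i]] + c2 * m[:, sec[i]]
        v2 = c1_i**2 + c2**2
        if i in spec.clique_regions:
            sys_i = sys_i + cq * q
            v2 += cq**2
        x[:, i] = (
            alpha * sys_i
            + np.sqrt(1 - alpha**2) * np.sqrt(v2) * priv
            + b * g
            + spec.noise_sd * eps[:, i]
        )

    for i, j in spec.hub_pairs():
        p = _band_unit(rng, T, 1, tr)[:, 0]
        x[:, i] += spec.hub_coupling * p
        x[:, j] += spec.hub_coupling * p

    for e in spec.planted_edges:
        amp = e.amp_patient if group == "patient" else e.amp_control
        p = _band_unit(rng, T, 1, tr)[:, 0]  # drawn regardless, keeps streams aligned
        if amp != 0:
            x[:, e.i] += amp * p
            x[:, e.j] += amp * p
    return x


def generate_motion(spec: CohortSpec, subject_index: int) -> np.ndarray:
    """Bounded random-walk rigid-body motion trace.

    AR(1) mean-reverting walks; translations scale with ``motion_scale``
    (mm), rotations with ``motion_scale / 50`` (radians), so both families
    contribute comparably to framewise displacement. The first
    ``qc_violator_fraction`` of subjects get 20x amplitude, guaranteeing
    they trip the 1.5 mm / 1.5 degree exclusion bounds.
    """
    if spec.n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = _subject_rng(spec, subject_index, 1)
    T = spec.n_volumes
    steps = rng.standard_normal((T, 6))
    walk = np.empty((T, 6))
    walk[0] = 0.0
    for t in range(1, T):
        walk[t] = 0.95 * walk[t - 1] + 0.2 * steps[t]
    scale = spec.motion_scale
    if spec.qc_violator_fraction > 0:
        n_violate = int(np.ceil(spec.qc_violator_fraction * spec.n_subjects))
        if subject_index < n_violate:
            scale *= 20.0
    out = walk * scale
    out[:, 3:] /= 50.0
    return out


def _covariates(spec: CohortSpec, subject_index: int, group: str) -> tuple[float, int, float]:
    """Age / sex / education with a patient-control age gap, mimicking the
    demographics of a middle-aged patient cohort against younger controls.
    Purely synthetic; exists to exercise covariate adjustment."""
    rng = _subject_rng(spec, subject_index, 2)
    mu_age = 55.0 if group == "patient" else 42.0
    age = float(np.clip(rng.normal(mu_age, 10.0), 18.0, 90.0))
    sex = int(rng.integers(0, 2))
    education = float(np.clip(rng.normal(12.0, 3.0), 0.0, 25.0))
    return age, sex, education


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort, patients first then controls.

    Deterministic given ``spec.seed``: every random stream is derived from
    (seed, subject index, stream id), so repeated calls are byte-identical
    and per-subject data do not depend on cohort size.
    """
    labels = (
        atlas.region_labels()
        if spec.n_regions == atlas.N_REGIONS
        else [f"R{i + 1:03d}" for i in range(spec.n_regions)]
    )
    records: list[SubjectRecord] = []
    for idx in range(spec.n_subjects):
        group = "patient" if idx < spec.n_patients else "control"
        prefix = "P" if group == "patient" else "C"
        values = generate_timeseries(spec, idx, group)
        motion = generate_motion(spec, idx)
        age, sex, edu = _covariates(spec, idx, group)
        records.append(
            SubjectRecord(
                subject_id=f"{prefix}{idx + 1:03d}",
                group=group,
                age=age,
                sex=sex,
                education=edu,
                timeseries=RoiTimeSeries(values, labels, spec.tr_seconds),
                motion=motion,
            )
        )
    return records


# ---------------------------------------------------------------------------
# on-disk layout: whitespace-delimited matrices plus a TSV manifest
# ---------------------------------------------------------------------------

def write_cohort(records: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write one time-series matrix and one motion file per subject plus a
    cohort manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    ts_dir = out_dir / "timeseries"
    mo_dir = out_dir / "motion"
    ts_dir.mkdir(parents=True, exist_ok=True)
    mo_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ts_path = ts_dir / f"{rec.subject_id}.tsv"
        mo_path = mo_dir / f"{rec.subject_id}_motion.tsv"
        np.savetxt(ts_path, rec.timeseries.values, fmt="%.6f", delimiter="\t")
        np.savetxt(mo_path, rec.motion, fmt="%.8f", delimiter="\t")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "age": round(rec.age, 2),
                "sex": rec.sex,
                "education": round(rec.education, 2),
                "timeseries_path": str(ts_path.relative_to(out_dir)),
                "motion_path": str(mo_path.relative_to(out_dir)),
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path, tr_seconds: float = 1.0) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t")
    records = []
    for _, row in df.iterrows():
        values = np.loadtxt(base / row["timeseries_path"])
        motion = np.loadtxt(base / row["motion_path"])
        if motion.ndim == 1:
            motion = motion.reshape(1, -1)
        labels = (
            atlas.region_labels()
            if values.shape[1] == atlas.N_REGIONS
            else [f"R{i + 1:03d}" for i in range(values.shape[1])]
        )
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=int(row["sex"]),
                education=float(row["education"]),
                timeseries=RoiTimeSeries(values, labels, tr_seconds),
                motion=motion,
            )
        )
    return records
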