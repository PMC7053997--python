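"""Synthetic trajectory and assay-data generation.

Real production MD of a liganded receptor is far outside desk scale, and the
analyses in this package only assume a particular statistical structure in
their inputs. This module generates data with exactly that structure:

* a toy receptor (~70 heavy atoms): pseudo-Calpha beads for the
  extracellular subsegments of the seven TM helices, a five-residue EL2
  stretch with full backbone atoms whose Ile183(O)-Asn186(N) anchor distance
  is ~2.9 A in the helical template and ~8 A in the extended template
  (straddling the 4 A classification threshold), a Trp100-analogue sidechain
  with poseable chi1/chi2 torsions, the three-Calpha Ile3.40 sub-pocket
  triad, and a single-atom ligand probe that sits in the sub-pocket in the
  helical-state template and outside it in the extended-state template;
* a two-state continuous-time Markov switching process between the
  templates, discretized exactly (per-frame switch probability
  1 - exp(-k * dt), so the rates are recoverable at any frame interval),
  with state-dependent von Mises rotamer draws and isotropic Gaussian
  coordinate noise;
* saturation and competition binding datasets from known true parameters
  plus Gaussian noise.

All randomness derives from one seed through named substreams (state path /
coordinate noise / rotamer draws), so the components can be varied
independently. What this generator does NOT emulate: force-field energetics,
solvent and membrane, correlated (non-isotropic) fluctuations, and any
coupling between the binding-site shape and the loop state beyond the
planted templates — conclusions from these data are about the estimators,
not about receptor biophysics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import FeatureSeries, Topology, Trajectory, write_multimodel_pdb
from .pharm import CompetitionDataset, SaturationDataset, _competition_model, _saturation_model

__all__ = [
    "ToyReceptorSpec",
    "SimConfig",
    "GeneratedDataset",
    "build_toy_receptor",
    "simulate_switching_trajectory",
    "generate_binding_data",
]

logger = logging.getLogger(__name__)

# Extracellular subsegment beads: 4 pseudo-Calpha residues per TM, numbered
# inside the receptor's subsegment ranges.
_TM_SEGMENTS = {
    "TM1e": 31, "TM2e": 92, "TM3e": 104, "TM4e": 166,
    "TM5e": 187, "TM6e": 364, "TM7e": 376,
}
_EL2_RESIDUES = (182, 183, 184, 185, 186)
_POCKET_RESIDUES = ((122, "ILE"), (198, "PHE"), (382, "PHE"))
_TRP_RESIDUE = 100
_LIGAND_RESIDUE = 900


@dataclass
class ToyReceptorSpec:
    """Topology plus the two state templates and named anchor atoms."""

    topology: Topology
    template_helical: np.ndarray
    template_extended: np.ndarray
    anchors: dict[str, int] = field(default_factory=dict)

    @property
    def templates(self) -> dict[str, np.ndarray]:
        return {"helical": self.template_helical, "extended": self.template_extended}

    def anchor_distance(self, state: str) -> float:
        t = self.templates[state]
        return float(np.linalg.norm(t[self.anchors["el2_O183"]] - t[self.anchors["el2_N186"]]))


@dataclass
class SimConfig:
    """Switching-simulation parameters.

    Defaults are the reference study conditions for the loop-dynamics
    recovery analyses: helical->extended rate 0.01/ns, extended->helical
    0.03/ns (stationary helical probability 0.75), 0.6 ns frame interval,
    50,000 frames, 0.3 A coordinate noise, chi1 rotamer means of -65 deg
    (gauche-) in the helical state and 178 deg (trans) in the extended state.
    """

    k_he: float = 0.01
    k_eh: float = 0.03
    frame_interval_ns: float = 0.6
    n_frames: int = 50_000
    noise_sigma: float = 0.3
    chi1_mean: dict = field(default_factory=lambda: {"helical": -65.0, "extended": 178.0})
    chi2_mean: dict = field(default_factory=lambda: {"helical": 90.0, "extended": 90.0})
    rotamer_kappa: float = 50.0
    initial_state: str | None = None  # None: draw from the stationary law
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_he < 0 or self.k_eh < 0 or (self.k_he == 0 and self.k_eh == 0):
            raise ConfigurationError("rates must be >= 0 and not both zero")
        if self.n_frames < 2:
            raise ConfigurationError("need at least 2 frames")
        if self.frame_interval_ns <= 0:
            raise ConfigurationError("frame interval must be positive")


@dataclass
class GeneratedDataset:
    """A simulated trajectory with its ground truth and config echo."""

    trajectory: Trajectory
    truth: pd.DataFrame  # frame, state, chi1, chi2
    config: SimConfig
    spec: ToyReceptorSpec

    def write(self, directory) -> None:
        """Persist as multi-model PDB + truth TSV + config JSON manifest."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_multimodel_pdb(self.trajectory, d / "trajectory.pdb")
        self.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        (d / "config.json").write_text(json.dumps(cfg, indent=2))

    def anchor_distance_series(self) -> FeatureSeries:
        from .geometry import interatomic_distance
        a = self.spec.anchors
        return interatomic_distance(self.trajectory, [a["el2_O183"]], [a["el2_N186"]],
                                    name="Ile183(O)-Asn186(N) distance")

    def chi1_series(self) -> FeatureSeries:
        from .geometry import dihedral
        a = self.spec.anchors
        return dihedral(self.trajectory, [a["trp_N"]], [a["trp_CA"]],
                        [a["trp_CB"]], [a["trp_CG"]], name="Trp100 chi1")


# ---------------------------------------------------------------------------
# Toy receptor construction
# ---------------------------------------------------------------------------

def _torsion(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2)
    return math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2n), np.dot(n1, n2)))


def build_toy_receptor(
    helical_anchor_distance: float = 2.9,
    extended_anchor_distance: float = 8.0,
    tm_shifts: dict[str, np.ndarray] | None = None,
) -> ToyReceptorSpec:
    """Deterministically construct the toy receptor templates.

    ``tm_shifts`` displaces whole TM subsegments (A vectors) in BOTH
    templates — used to plant a distinct binding-site conformation for a
    second simulated condition.
    """
    names, res_seq, res_name, elements = [], [], [], []
    coords: list[np.ndarray] = []

    def add(name, rseq, rname, elem, xyz):
        names.append(name); res_seq.append(rseq); res_name.append(rname)
        elements.append(elem); coords.append(np.asarray(xyz, dtype=float))

    # TM subsegment beads on a 12 A circle, 4 beads per segment stacked in z
    for s, (seg, first) in enumerate(_TM_SEGMENTS.items()):
        ang = 2.0 * math.pi * s / 7.0
        cx, cy = 12.0 * math.cos(ang), 12.0 * math.sin(ang)
        for i in range(4):
            add("CA", first + i, "ALA", "C", (cx, cy, 1.5 * i))

    # EL2 backbone: helical template on a tight helix, extended on a line.
    def el2_backbone(kind: str) -> dict[int, dict[str, np.ndarray]]:
        out = {}
        for j, r in enumerate(_EL2_RESIDUES):
            if kind == "helical":
                th = math.radians(100.0 * j)
                base = np.array([2.3 * math.cos(th), 6.0 + 2.3 * math.sin(th), 8.0 + 1.5 * j])
                tang = np.array([-math.sin(th), math.cos(th), 0.65])
            else:
                base = np.array([-1.0 + 3.5 * j, 9.0, 9.0])
                tang = np.array([1.0, 0.0, 0.0])
            tang = tang / np.linalg.norm(tang)
            up = np.array([0.0, 0.0, 1.0])
            perp = np.cross(tang, up)
            perp /= np.linalg.norm(perp)
            out[r] = {
                "N": base - 0.7 * tang,
                "CA": base,
                "C": base + 0.7 * tang,
                "O": base + 0.7 * tang + 1.2 * perp,
            }
        return out

    bb = {"helical": el2_backbone("helical"), "extended": el2_backbone("extended")}
    # pin the Ile183(O)-Asn186(N) anchor distance exactly per template
    for kind, target in (("helical", helical_anchor_distance),
                         ("extended", extended_anchor_distance)):
        o, nn = bb[kind][183]["O"], bb[kind][186]["N"]
        u = (o - nn) / np.linalg.norm(o - nn)
        bb[kind][183]["O"] = nn + target * u

    el2_start = len(coords)
    for r in _EL2_RESIDUES:
        rname = {182: "CYS", 183: "ILE", 184: "ILE", 185: "ALA", 186: "ASN"}[r]
        for an, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            add(an, r, rname, el, bb["helical"][r][an])

    # Trp100 analogue: backbone N/CA + sidechain CB, CG, CD1, CD2
    trp_origin = np.array([8.0, 8.0, 6.0])
    add("N", _TRP_RESIDUE, "TRP", "N", trp_origin + (-1.2, -0.6, 0.0))
    add("CA", _TRP_RESIDUE, "TRP", "C", trp_origin)
    add("CB", _TRP_RESIDUE, "TRP", "C", trp_origin + (0.6, 1.1, 0.9))
    # CG placed off-axis so chi1 is well defined; CD1/CD2 hang off CG
    add("CG", _TRP_RESIDUE, "TRP", "C", trp_origin + (0.4, 2.5, 1.4))
    add("CD1", _TRP_RESIDUE, "TRP", "C", trp_origin + (1.3, 3.4, 1.9))
    add("CD2", _TRP_RESIDUE, "TRP", "C", trp_origin + (-0.8, 3.1, 1.6))

    # Ile3.40 sub-pocket triad (Calpha atoms)
    pocket_center = np.array([0.0, 0.0, -5.0])
    for k, (r, rname) in enumerate(_POCKET_RESIDUES):
        th = 2.0 * math.pi * k / 3.0
        add("CA", r, rname, "C", pocket_center + (3.0 * math.cos(th), 3.0 * math.sin(th), 0.0))

    # ligand probe: inside the pocket in the helical template (3.5 A from the
    # triad centroid), outside it in the extended template (7 A away)
    probe_idx = len(coords)
    add("C1", _LIGAND_RESIDUE, "LIG", "C", pocket_center + (0.0, 0.0, 3.5))

    top = Topology(tuple(names), tuple(res_seq), tuple(res_name),
                   tuple(["A"] * len(names)), tuple(elements))
    helical = np.array(coords)
    extended = helical.copy()
    for j, r in enumerate(_EL2_RESIDUES):
        for a, an in enumerate(("N", "CA", "C", "O")):
            extended[el2_start + 4 * j + a] = bb["extended"][r][an]
    extended[probe_idx] = pocket_center + (0.0, 0.0, 7.0)

    if tm_shifts:
        name_arr = np.array(top.atom_names)
        rs = np.array(top.residue_seq)
        for seg, shift in tm_shifts.items():
            if seg not in _TM_SEGMENTS:
                raise ConfigurationError(f"unknown subsegment {seg!r}")
            first = _TM_SEGMENTS[seg]
            mask = (rs >= first) & (rs < first + 4) & (name_arr == "CA")
            helical[mask] += np.asarray(shift, dtype=float)
            extended[mask] += np.asarray(shift, dtype=float)

    def atom(name, rseq):
        for i in range(top.n_atoms):
            if top.atom_names[i] == name and top.residue_seq[i] == rseq:
                return i
        raise ConfigurationError(f"atom {name} {rseq} not found")  # pragma: no cover

    anchors = {
        "el2_O183": atom("O", 183), "el2_N186": atom("N", 186),
        "trp_N": atom("N", _TRP_RESIDUE), "trp_CA": atom("CA", _TRP_RESIDUE),
        "trp_CB": atom("CB", _TRP_RESIDUE), "trp_CG": atom("CG", _TRP_RESIDUE),
        "trp_CD1": atom("CD1", _TRP_RESIDUE), "trp_CD2": atom("CD2", _TRP_RESIDUE),
        "pocket": tuple(atom("CA", r) for r, _ in _POCKET_RESIDUES),
        "probe": probe_idx,
    }
    return ToyReceptorSpec(top, helical, extended, anchors)


# ---------------------------------------------------------------------------
# Switching simulation
# ---------------------------------------------------------------------------

def _rodrigues(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
               angle_rad: np.ndarray) -> np.ndarray:
    """Batched rotation of ``points`` (f, m, 3) about per-frame axes."""
    v = points - origin[:, None, :]
    k = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    c = np.cos(angle_rad)[:, None, None]
    s = np.sin(angle_rad)[:, None, None]
    kxv = np.cross(np.broadcast_to(k[:, None, :], v.shape), v)
    kdv = np.einsum("fj,fmj->fm", k, v)[:, :, None]
    rot = v * c + kxv * s + k[:, None, :] * kdv * (1 - c)
    return rot + origin[:, None, :]


def simulate_switching_trajectory(spec: ToyReceptorSpec, config: SimConfig) -> GeneratedDataset:
    """Simulate the two-state switching trajectory.

    The state path is a discretized continuous-time Markov chain: at each
    frame the chain leaves its state with probability ``1 - exp(-k * dt)``.
    Frame coordinates are the current state's template with the Trp chi1/chi2
    torsions set from state-dependent von Mises draws, plus isotropic
    Gaussian noise on every atom.
    """
    sep = abs(spec.anchor_distance("extended") - spec.anchor_distance("helical"))
    if config.noise_sigma > sep / 2.0:
        logger.warning("noise sigma %.2f A exceeds half the template separation %.2f A: "
                       "states may be indistinguishable", config.noise_sigma, sep)

    ss = np.random.SeedSequence(config.seed)
    rng_path, rng_noise, rng_rot = (np.random.default_rng(s) for s in ss.spawn(3))

    dt = config.frame_interval_ns
    p_he = 1.0 - math.exp(-config.k_he * dt)
    p_eh = 1.0 - math.exp(-config.k_eh * dt)

    states = np.empty(config.n_frames, dtype=int)  # 0 = helical, 1 = extended
    if config.initial_state is None:
        pi_h = config.k_eh / (config.k_he + config.k_eh)
        states[0] = 0 if rng_path.random() < pi_h else 1
    else:
        states[0] = {"helical": 0, "extended": 1}[config.initial_state]
    u = rng_path.random(config.n_frames - 1)
    for t in range(1, config.n_frames):
        p = p_he if states[t - 1] == 0 else p_eh
        states[t] = states[t - 1] ^ (u[t - 1] < p)

    chi1 = np.degrees(rng_rot.vonmises(
        np.radians([config.chi1_mean["helical"], config.chi1_mean["extended"]])[states],
        config.rotamer_kappa))
    chi2 = np.degrees(rng_rot.vonmises(
        np.radians([config.chi2_mean["helical"], config.chi2_mean["extended"]])[states],
        config.rotamer_kappa))

    templates = np.stack([spec.template_helical, spec.template_extended])
    coords = templates[states].copy()

    a = spec.anchors
    ref_chi1 = {s: _torsion(templates[s][a["trp_N"]], templates[s][a["trp_CA"]],
                            templates[s][a["trp_CB"]], templates[s][a["trp_CG"]])
                for s in (0, 1)}
    ref_chi2 = {s: _torsion(templates[s][a["trp_CA"]], templates[s][a["trp_CB"]],
                            templates[s][a["trp_CG"]], templates[s][a["trp_CD1"]])
                for s in (0, 1)}

    # chi1: rotate the CG subtree about the CA->CB axis
    d1 = np.radians(chi1 - np.array([ref_chi1[0], ref_chi1[1]])[states])
    sub1 = [a["trp_CG"], a["trp_CD1"], a["trp_CD2"]]
    coords[:, sub1] = _rodrigues(coords[:, sub1], coords[:, a["trp_CB"]],
                                 coords[:, a["trp_CB"]] - coords[:, a["trp_CA"]], d1)
    # chi2: rotate CD1/CD2 about the CB->CG axis
    d2 = np.radians(chi2 - np.array([ref_chi2[0], ref_chi2[1]])[states])
    sub2 = [a["trp_CD1"], a["trp_CD2"]]
    coords[:, sub2] = _rodrigues(coords[:, sub2], coords[:, a["trp_CG"]],
                                 coords[:, a["trp_CG"]] - coords[:, a["trp_CB"]], d2)

    if config.noise_sigma > 0:
        coords += rng_noise.normal(0.0, config.noise_sigma, size=coords.shape)

    traj = Trajectory(spec.topology, coords, config.frame_interval_ns)
    truth = pd.DataFrame({
        "frame": np.arange(config.n_frames),
        "state": np.array(["helical", "extended"])[states],
        "chi1": chi1, "chi2": chi2,
    })
    return GeneratedDataset(traj, truth, config, spec)


# ---------------------------------------------------------------------------
# Assay data generation
# ---------------------------------------------------------------------------

def generate_binding_data(
    kind: str,
    true_params: dict[str, float],
    design: dict | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
):
    """Simulate a saturation or competition dataset from known parameters.

    ``kind`` is "saturation" (params Bmax, KA, NS; design key ``conc_nM``)
    or "competition" (params Top, Bottom, logIC50, nH; design keys
    ``conc_nM``, ``tracer_conc_nM``, ``tracer_kd_nM``). ``replicates``
    (default 3) repeats each concentration, emulating wells run in
    triplicate. Responses are the exact model values plus Gaussian noise of
    sd ``noise_sigma`` (response units); seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    design = design or {}
    reps = int(design.get("replicates", 3))
    if kind == "saturation":
        conc = np.asarray(design.get("conc_nM",
                                     np.geomspace(0.01, 10.0, 10)), dtype=float)
        conc = np.repeat(conc, reps)
        tot = _saturation_model(conc, true_params["Bmax"], true_params["KA"],
                                true_params["NS"])
        nsb = true_params["NS"] * conc
        if noise_sigma > 0:
            tot = tot + rng.normal(0, noise_sigma, conc.shape)
            nsb = nsb + rng.normal(0, noise_sigma, conc.shape)
        return SaturationDataset(conc, tot, nsb)
    if kind == "competition":
        conc = np.asarray(design.get("conc_nM",
                                     np.geomspace(1e-3, 1e5, 12)), dtype=float)
        conc = np.repeat(conc, reps)
        y = _competition_model(np.log10(conc), true_params["Top"],
                               true_params["Bottom"], true_params["logIC50"],
                               true_params["nH"])
        if noise_sigma > 0:
            y = y + rng.normal(0, noise_sigma, conc.shape)
        return CompetitionDataset(conc, y,
                                  float(design.get("tracer_conc_nM", 0.2)),
                                  float(design.get("tracer_kd_nM", 0.18)))
    raise ConfigurationError(f"unknown dataset kind {kind!r}")
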