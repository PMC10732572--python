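"""Synthetic assay data with known ground truth.

Each generator wraps the corresponding forward model and adds (optionally
zero) Gaussian noise under a reproducible per-dataset RNG derived from
(master seed, assay name, replicate index).  Defaults reproduce the study
conditions the fitters are meant to recover: the VP-ITC protocol (1.4619 ml
cell, 110 uM macromolecule, 1.5 mM titrant), 0-300 mM cation titrations,
300 s / 300 s sensograms at 50 uM analyte, GTPgammaS progress curves across
the 0, 0.25, 0.375, 0.425, 1, 10, 25, 50, 500 uM CaCl2 series, and 35-95
degC melt scans.

Ground truth travels alongside each dataset in the generator's return value
(and in `.truth.json` sidecar files when written to disk) so recovery can be
scored without ever feeding the truth to a fitter.

Default noise levels (used when a spec requests "realistic" noise): ITC 2%
of the peak |heat|, titration/BLI/exchange 2-3% of the signal amplitude,
melt curves 0.5% of the ratio range — chosen to resemble published
instrument scatter; they are conventions, not measurements.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .bli import Sensogram, simulate_sensogram
from .equilibria import SequentialBindingModel
from .exchange import ProgressCurve, activation_velocity
from .interface import Atom, Structure
from .itc import ITCProtocol, Isotherm, simulate_isotherm
from .thermal import MeltCurve, two_state_ratio_curve
from .titration import TitrationCurve

__all__ = [
    "GeneratorSpec",
    "PRESETS",
    "dataset_rng",
    "gen_itc",
    "gen_titration",
    "gen_sensogram",
    "gen_progress",
    "gen_melt",
    "gen_toy_complex",
    "write_truth_sidecar",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """What to generate: assay kind, truth, protocol, noise and seed."""

    assay: str
    truth: dict
    protocol: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    noise_relative: bool = False
    seed: int = 0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def dataset_rng(master_seed: int, assay: str, replicate: int = 0) -> np.random.Generator:
    """Per-dataset RNG: seed derived from (master seed, assay, replicate).

    The assay label enters through a CRC so different assays under one
    master seed draw independent streams, reproducibly across sessions.
    """
    tag = zlib.crc32(assay.encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag, replicate]))


# --------------------------------------------------------------- presets

_CA_SERIES_REF = tuple(c * 1e-6 for c in (0, 1, 10, 25, 50, 500))
_CA_SERIES_COMPLEX = tuple(
    c * 1e-6 for c in (0, 0.25, 0.375, 0.425, 1, 10, 25, 50, 500)
)

#: Ground-truth parameter sets matching the published assay conditions.
PRESETS: dict[str, dict] = {
    # sequential Ca2+ ITC, Na+- and K+-buffer conditions
    "table4_na": {
        "assay": "itc",
        "kd": (265e-9, 758e-9, 379e-9),
        "dh": (-7.7, 3.0, -9.1),
    },
    "table4_k": {
        "assay": "itc",
        "kd": (165.6e-9, 362.3e-9, 253e-9),
        "dh": (-7.66, 1.00, -9.44),
    },
    # 1:1 cation fluorescence titrations
    "titration_na": {"assay": "titration", "kd_app": 123.4e-3, "y_max": 1.0},
    "titration_k": {"assay": "titration", "slope": 0.8, "intercept": 0.0},
    # BLI sensograms per Ca2+ condition (apparent Kd, molar)
    "table3_ca0": {"assay": "bli", "kd_app": 140e-6, "k_on": 1e3},
    "table3_ca250": {"assay": "bli", "kd_app": 344e-6, "k_on": 1e3},
    "table3_ca375": {"assay": "bli", "kd_app": 381e-6, "k_on": 1e3},
    "table3_ca425": {"assay": "bli", "kd_app": 98620e-6, "k_on": 1e3},
    # Ca2+ activation of nucleotide exchange
    "ka_exc": {
        "assay": "activation",
        "ka": 29e-6, "v0": 0.002, "v_max": 0.006,
        "ca_series": _CA_SERIES_REF,
    },
    "ka_ncs1": {
        "assay": "activation",
        "ka": 61e-6, "v0": 0.001, "v_max": 0.004,
        "ca_series": _CA_SERIES_COMPLEX,
    },
    # nano-DSF inflection temperatures (degC)
    "ti_panel": {
        "assay": "melt",
        "samples": {
            "ric8a_free": 53.5,
            "ncs1_egta": 58.4,
            "ric8a_complexed": 79.7,
            "ncs1_complexed": 82.8,
        },
        "dh_vh": 100.0,
    },
}


# --------------------------------------------------------------- generators

def gen_itc(spec: GeneratorSpec) -> tuple[Isotherm, dict]:
    """Sequential-model isotherm with additive Gaussian noise on q_per_mol."""
    truth = dict(spec.truth)
    model = SequentialBindingModel(kd=tuple(truth["kd"]), dh=tuple(truth["dh"]))
    protocol = ITCProtocol(**spec.protocol)
    iso = simulate_isotherm(model, protocol)
    q = iso.q_per_mol.copy()
    if spec.noise_sd > 0:
        rng = dataset_rng(spec.seed, "itc", spec.replicate)
        sd = spec.noise_sd * np.max(np.abs(q)) if spec.noise_relative else spec.noise_sd
        q = q + rng.normal(0.0, sd, q.size)
    noisy = Isotherm(iso.molar_ratio, q, q * protocol.syringe_conc
                     * protocol.injection_volumes, protocol)
    return noisy, truth


def gen_titration(spec: GeneratorSpec) -> tuple[TitrationCurve, dict]:
    """Saturating (kd_app, y_max) or linear (slope, intercept) titration."""
    truth = dict(spec.truth)
    conc = np.asarray(
        spec.protocol.get("conc_grid", np.linspace(0.0, 300e-3, 15)), dtype=float
    )
    if "kd_app" in truth:
        y = truth.get("y_max", 1.0) * conc / (truth["kd_app"] + conc)
    else:
        y = truth.get("slope", 1.0) * conc + truth.get("intercept", 0.0)
    if spec.noise_sd > 0:
        rng = dataset_rng(spec.seed, "titration", spec.replicate)
        scale = np.max(np.abs(y)) if spec.noise_relative and np.max(np.abs(y)) > 0 else 1.0
        y = y + rng.normal(0.0, spec.noise_sd * (scale if spec.noise_relative else 1.0),
                           y.size)
    return TitrationCurve(conc, y, replicate=f"r{spec.replicate}"), truth


def gen_sensogram(spec: GeneratorSpec) -> tuple[Sensogram, dict]:
    """1:1 Langmuir sensogram; truth gives kd_app + k_on (or k_on + k_off)."""
    truth = dict(spec.truth)
    k_on = truth.get("k_on", 1e3)
    k_off = truth["k_off"] if "k_off" in truth else truth["kd_app"] * k_on
    truth.setdefault("k_off", k_off)
    truth.setdefault("kd_app", k_off / k_on)
    p = dict(spec.protocol)
    s = simulate_sensogram(
        k_on, k_off, p.get("r_max", 1.0), p.get("analyte_conc", 50e-6),
        t_assoc=p.get("t_assoc", 300.0), t_dissoc=p.get("t_dissoc", 300.0),
        dt=p.get("dt", 0.5), t_baseline=p.get("t_baseline", 0.0),
    )
    shift = s.shift.copy()
    if spec.noise_sd > 0:
        rng = dataset_rng(spec.seed, "bli", spec.replicate)
        sd = spec.noise_sd * np.max(np.abs(shift)) if spec.noise_relative else spec.noise_sd
        shift = shift + rng.normal(0.0, sd, shift.size)
    noisy = Sensogram(s.time, shift, s.phase, s.analyte_conc, s.t_assoc_start)
    return noisy, truth


def gen_progress(spec: GeneratorSpec) -> tuple[list[ProgressCurve], dict]:
    """GTPgammaS progress curves across a CaCl2 series.

    The catalysed rate at each concentration follows the activation
    hyperbola in the truth (v0, v_max, ka); each curve is a rising
    exponential F = f0 + a (1 - exp(-k t)).
    """
    truth = dict(spec.truth)
    ca = np.asarray(truth.get("ca_series", _CA_SERIES_REF), dtype=float)
    rates = activation_velocity(ca, truth["v0"], truth["v_max"], truth["ka"])
    t = np.asarray(spec.protocol.get("t_grid", np.linspace(0.0, 1800.0, 240)))
    f0 = spec.protocol.get("f0", 1.0)
    amp = spec.protocol.get("amplitude", 0.5)
    curves = []
    rng = dataset_rng(spec.seed, "exchange", spec.replicate)
    for i, (c, k) in enumerate(zip(ca, rates)):
        f = f0 + amp * (1.0 - np.exp(-k * t))
        if spec.noise_sd > 0:
            sd = spec.noise_sd * amp if spec.noise_relative else spec.noise_sd
            f = f + rng.normal(0.0, sd, f.size)
        curves.append(ProgressCurve(t, f, condition=f"ca_{c * 1e6:g}uM", ca_conc=float(c)))
    truth["rates"] = rates.tolist()
    return curves, truth


def gen_melt(spec: GeneratorSpec) -> tuple[list[MeltCurve], dict]:
    """Two-state melt curve(s); truth maps sample label -> midpoint (degC)."""
    truth = dict(spec.truth)
    samples = truth.get("samples") or {truth.get("sample", "s1"): truth["tm"]}
    dh_vh = truth.get("dh_vh", 100.0)
    p = dict(spec.protocol)
    t_grid = p.get("t_grid")
    curves = []
    rng = dataset_rng(spec.seed, "melt", spec.replicate)
    for label, tm in samples.items():
        c = two_state_ratio_curve(
            tm, dh_vh,
            folded_baseline=tuple(p.get("folded_baseline", (0.8, 0.0))),
            unfolded_baseline=tuple(p.get("unfolded_baseline", (1.0, 0.0))),
            t_grid=t_grid, sample=label,
        )
        r = c.ratio.copy()
        if spec.noise_sd > 0:
            sd = spec.noise_sd * np.ptp(r) if spec.noise_relative else spec.noise_sd
            r = r + rng.normal(0.0, sd, r.size)
        curves.append(MeltCurve(c.temperature, r, label))
    return curves, truth


def gen_toy_complex(
    n_atoms: int = 100,
    n_contacts_target: int = 25,
    seed: int = 0,
    cutoff: float = 4.2,
) -> tuple[Structure, int]:
    """Random two-chain structure with an engineered contact count.

    Chains A and B are placed in slabs separated by more than the cutoff, so
    no accidental inter-chain contact exists; then ``n_contacts_target``
    dedicated atom pairs are added with one atom per chain at a distance
    drawn inside the cutoff and far (> 2*cutoff) from everything else.  The
    returned count is therefore exact by construction.
    """
    rng = dataset_rng(seed, "toy_complex")
    n_half = n_atoms // 2
    gap = 3.0 * cutoff
    atoms: list[Atom] = []

    def add(chain, idx, xyz):
        atoms.append(Atom(chain=chain, res_seq=idx + 1, icode="",
                          res_name="ALA", name="CA" if idx % 2 else "CB",
                          element="C", xyz=tuple(np.round(xyz, 3))))

    # bulk slabs: chain A at z in [0, 20], chain B at z in [20+gap, 40+gap]
    for i in range(n_half):
        add("A", i, rng.uniform([0, 0, 0], [40, 40, 20]))
    for i in range(n_half):
        add("B", i, rng.uniform([0, 0, 20 + gap], [40, 40, 40 + gap]))

    # engineered contact pairs on a sparse lattice far from the slabs
    for k in range(n_contacts_target):
        base = np.array([60.0 + 3.0 * gap * k, 0.0, 0.0])
        d = rng.uniform(0.4 * cutoff, 0.95 * cutoff)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        add("A", n_half + k, base)
        add("B", n_half + k, base + d * u)

    struct = Structure(atoms, name=f"toy_complex_seed{seed}")
    return struct, n_contacts_target


def write_truth_sidecar(path: str | Path, truth: dict) -> Path:
    """Write ground truth next to a dataset as ``<stem>.truth.json``.

    Keeping the truth in a separate, clearly named file is what stops it
    from ever being read as fitter input.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    with open(sidecar, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=2)
    return sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
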