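"""Built-in validation scenarios.

Standard phantom configurations used to validate the pipeline end to end
against known ground truth: a mixed-class fixed-mode phantom, a filopodium
length-filter phantom, a scripted remodeling time series, and a fate-offset
series in which pruned mushroom spines are generated with systematically
thinner necks. Tests and the acceptance script share these definitions so
the study conditions are stated once.

All spine templates keep comfortable margins from the classification
boundaries (ratio 1.5, length 1 um) so that class recovery is well-posed at
the imaging resolution.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .phantom import PhantomSpec, RemodelScript, SpineEvent, SpineSpec

__all__ = [
    "mixed_phantom_spec", "filopodium_spec", "remodeling_script",
    "fate_offset_script", "identity_agreement", "SNR",
]

#: benchmark noise level: Gaussian sigma = (foreground - background) / SNR
SNR = 10.0

# class templates (length, head, neck) um — fixed-mode set
_TEMPLATES = [
    ("mushroom", 1.5, 0.60, 0.20),
    ("stubby", 0.8, 0.48, 0.40),
    ("thin", 2.5, 0.30, 0.25),
    ("mushroom", 1.8, 0.55, 0.22),
    ("stubby", 0.9, 0.45, 0.35),
    ("thin", 3.2, 0.32, 0.26),
]


def _azimuths(n, spread=0.5):
    """Azimuths spread around +/- pi/2 (in-plane) with bounded z excursion."""
    base = np.where(np.arange(n) % 2 == 0, np.pi / 2, -np.pi / 2)
    jit = ((np.arange(n) * 0.37) % 1.0 - 0.5) * 2 * spread
    return base + jit


def mixed_phantom_spec(n_spines: int = 20, dendrite_um: float = 50.0,
                       noisy: bool = False, seed: int = 0) -> PhantomSpec:
    """Noiseless (or SNR-10) phantom with mixed spine classes, >=1 um apart."""
    margin = 2.4
    s = np.linspace(margin, dendrite_um - margin, n_spines)
    az = _azimuths(n_spines)
    spines = [
        SpineSpec(attachment_arclength=si, azimuth=ai,
                  length=t[1], head_diameter=t[2], neck_diameter=t[3],
                  shape_class=t[0])
        for si, ai, t in zip(s, az, [_TEMPLATES[i % 6] for i in range(n_spines)])
    ]
    bg, fg = 100.0, 1000.0
    return PhantomSpec(
        field_of_view=(4.4, 8.8, dendrite_um + 2.0),
        spines=spines,
        background=bg, foreground=fg,
        noise=("gaussian", (fg - bg) / SNR) if noisy else None,
        seed=seed,
    )


def filopodium_spec(length_um: float = 6.0, seed: int = 0) -> PhantomSpec:
    """A single 6-um protrusion: excluded in fixed mode, kept in live mode."""
    sp = SpineSpec(attachment_arclength=10.0, azimuth=np.pi / 2,
                   length=length_um, head_diameter=0.35, neck_diameter=0.30)
    return PhantomSpec(
        field_of_view=(3.2, 2 * (0.8 + length_um + 0.6), 20.0),
        spines=[sp], seed=seed,
    )


def remodeling_script(seed: int = 0, n_time: int = 13,
                      morph_t: int = 6):
    """10 thin protrusions at t0: 4 morph to mushroom, 3 pruned, 3 stable.

    Returns ``(PhantomSpec, RemodelScript)``. Spacing (2.4 um) exceeds twice
    the tracking gate and jitter (0.1 um/step) stays below half the gate, so
    identity recovery is well-posed.
    """
    n = 10
    s = np.linspace(2.4, 2.4 * n, n)
    az = _azimuths(n, spread=0.25)
    thin = dict(length=2.5, head_diameter=0.36, neck_diameter=0.30)
    spines = [
        SpineSpec(attachment_arclength=si, azimuth=ai, shape_class="thin",
                  **thin)
        for si, ai in zip(s, az)
    ]
    mushroom_geom = {"length": 1.8, "head_diameter": 0.60,
                     "neck_diameter": 0.25}
    events = {}
    for sid in range(4):
        events[sid] = [SpineEvent("morph", morph_t, mushroom_geom)]
    for sid in range(4, 7):
        events[sid] = [SpineEvent("prune", morph_t)]
    spec = PhantomSpec(
        field_of_view=(4.6, 7.6, 2.4 * n + 4.0),
        spines=spines, seed=seed,
        psf_sigma=(0.12, 0.08, 0.08),
    )
    script = RemodelScript(n_time=n_time, jitter_amplitude=0.1, events=events)
    return spec, script


def fate_offset_script(seed: int = 0, n_time: int = 3,
                       neck_offset: float = 0.10):
    """Mushroom population where pruned spines have thinner necks.

    8 stable mushrooms (necks around 0.30 um) and 6 pruned ones (necks
    thinner by ``neck_offset``), pruned mid-series. Individual geometry
    varies around the group means (SDs on the order of the automated-method
    population spread) so group comparisons carry realistic sampling error.
    Returns ``(spec, script, neck_offset)`` for parameter-recovery tests on
    fate-group means.
    """
    n = 14
    rng = np.random.default_rng(seed + 20_000)
    s = np.linspace(2.2, 2.2 * n, n)
    az = _azimuths(n, spread=0.25)
    pruned_ids = set(list(range(1, n, 2))[:6])
    spines = []
    for i, (si, ai) in enumerate(zip(s, az)):
        neck = 0.30 - (neck_offset if i in pruned_ids else 0.0)
        neck = float(np.clip(neck + rng.normal(0, 0.025), 0.16, 0.40))
        head = float(np.clip(0.64 + rng.normal(0, 0.03), 0.55, 0.74))
        # keep a clear mushroom margin (head/neck well above the 1.5 boundary)
        neck = min(neck, head / 1.9)
        length = float(np.clip(1.6 + rng.normal(0, 0.12), 1.25, 2.0))
        spines.append(SpineSpec(
            attachment_arclength=si, azimuth=ai, shape_class="mushroom",
            length=length, head_diameter=head, neck_diameter=neck,
        ))
    events = {i: [SpineEvent("prune", n_time - 1)] for i in pruned_ids}
    spec = PhantomSpec(
        field_of_view=(4.2, 6.4, 2.2 * n + 4.0),
        spines=spines, seed=seed,
        psf_sigma=(0.12, 0.08, 0.08),
    )
    script = RemodelScript(n_time=n_time, jitter_amplitude=0.05,
                           events=events)
    return spec, script, neck_offset


def identity_agreement(tracks, records_per_time, truth, tol: float = 0.5):
    """Fraction of ground-truth spines recovered as one identity-consistent
    track spanning exactly the true presence interval."""
    from .validate import score_detection

    # per-frame map: record object -> truth spine id
    rec_to_truth = {}
    for t, recs in enumerate(records_per_time):
        sub = truth[(truth["time"] == t) & truth["present"].astype(bool)]
        sub = sub.reset_index(drop=True)
        score = score_detection(recs, sub, tol=tol)
        for _, row in score.errors.iterrows():
            rec = next(r for r in recs if r.id == row["det_id"])
            rec_to_truth[id(rec)] = int(row["truth_id"])
    ok = 0
    truth_ids = sorted(truth["spine_id"].unique())
    for sid in truth_ids:
        frames = set(
            truth[(truth["spine_id"] == sid)
                  & truth["present"].astype(bool)]["time"]
        )
        owners = [
            tr for tr in tracks
            if any(rec_to_truth.get(id(r)) == sid for r in tr.records.values())
        ]
        if len(owners) != 1:
            continue
        tr = owners[0]
        ids = {rec_to_truth.get(id(r)) for r in tr.records.values()}
        if ids == {sid} and set(tr.records) == frames:
            ok += 1
    return ok / len(truth_ids) if truth_ids else float("nan")
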