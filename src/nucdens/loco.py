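"""LOcal COmparison (LOCO) rules: is a vibrational excitation visible?

For each nucleus, the spatial extents and directions of the normal-mode
displacements at that nucleus are compared.  A node introduced by exciting
mode k shows up in the one-nucleus density only if no other mode smears
the same direction too strongly:

* rule a (visible): mode k is the only mode displacing the nucleus in its
  direction, or it dominates the competitors there.
* rule b (masked): competitor modes displace the nucleus in the same
  direction with comparable or larger extent, filling the depletion.
* rule c (combination): two or more *excited* modes share a direction at
  the nucleus; the density shows combination features there.

The comparison uses amplitude-scaled displacements
``sigma_jk = |d_jk| / sqrt(2 omega_k)`` — the ground-state positional
spread the mode contributes at nucleus j — rather than bare eigenvector
components, because visibility is a competition of spatial widths.  The
masking threshold is derived, not fitted: a 1D first-excited-state dip
convolved with a transverse Gaussian of width sigma_c retains its two
strict maxima iff sigma_c^2 < 2 sigma_k^2, so an excitation is masked when
the summed projected competitor variance reaches twice the excited mode's
variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .harmonic import NormalModeSet
from .system import MolecularSystem, VibrationalState


@dataclass(frozen=True)
class ModeDisplacement:
    """Cartesian displacement of one nucleus along one vibrational mode.

    ``d`` is the nucleus-j block of ``M^{-1/2} L[:, k]`` (bohr per unit
    mass-weighted normal coordinate); ``omega`` the mode frequency.
    ``sigma`` is the spatial ground-state spread |d|/sqrt(2 omega).
    """

    nucleus: int
    mode: int
    d: np.ndarray
    omega: float

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.d))

    @property
    def sigma(self) -> float:
        return self.magnitude / math.sqrt(2.0 * self.omega)

    @property
    def direction(self) -> np.ndarray:
        m = self.magnitude
        return self.d / m if m > 0 else np.zeros(3)


@dataclass(frozen=True)
class LocoThresholds:
    """Tunable parameters of the LOCO comparison.

    cos_thresh
        |cos angle| above which two displacements count as "the same
        direction" (default 0.9).
    mask_variance_ratio
        Masked when the summed projected competitor variance is at least
        this multiple of the excited mode's variance.  The default 2.0 is
        the closed-form threshold at which a transverse Gaussian erases the
        strict maxima of a first-excited-state dip.
    negligible_ratio
        A mode whose extent at the nucleus is below this fraction of the
        largest extent there cannot produce a visible change.
    """

    cos_thresh: float = 0.9
    mask_variance_ratio: float = 2.0
    negligible_ratio: float = 0.05


@dataclass(frozen=True)
class LocoVerdict:
    nucleus: int
    excited_modes: tuple
    verdict: str  # visible | masked | combination
    competing_modes: tuple
    rationale: str  # rule_a | rule_b | rule_c

    def to_dict(self) -> dict:
        return {
            "nucleus": self.nucleus,
            "excited_modes": list(self.excited_modes),
            "verdict": self.verdict,
            "competing_modes": list(self.competing_modes),
            "rationale": self.rationale,
        }


def mode_displacements(modes: NormalModeSet, system: MolecularSystem):
    """Per-(nucleus, vibrational mode) displacement vectors.

    Translation/rotation modes are excluded: they localize the molecule
    and carry no vibrational excitation.
    """
    inv_sqrt_m = 1.0 / np.sqrt(system.masses_3n)
    D = inv_sqrt_m[:, None] * modes.L
    out = []
    for k in modes.vibrational_indices:
        for j in range(system.n_nuclei):
            out.append(
                ModeDisplacement(
                    nucleus=j,
                    mode=k,
                    d=D[3 * j : 3 * j + 3, k].copy(),
                    omega=float(modes.omega[k]),
                )
            )
    return out


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def loco_predict(
    displacements,
    excited_modes,
    nucleus: int,
    thresholds: LocoThresholds | None = None,
) -> LocoVerdict:
    """Predict visibility of an excitation at one nucleus.

    ``displacements`` must cover all vibrational modes (from
    :func:`mode_displacements`); ``excited_modes`` is the set of excited
    vibrational mode indices.
    """
    th = thresholds or LocoThresholds()
    at_nucleus = {md.mode: md for md in displacements if md.nucleus == nucleus}
    excited = sorted(set(int(k) for k in excited_modes))
    if not excited:
        raise ValueError("at least one excited mode required")
    for k in excited:
        if k not in at_nucleus:
            raise ValueError(f"unknown or non-vibrational mode index {k}")

    sigma_max = max(md.sigma for md in at_nucleus.values())

    # rule c: two or more excited modes sharing a direction at this nucleus
    if len(excited) > 1:
        sharing = set()
        for i, a in enumerate(excited):
            for b in excited[i + 1 :]:
                da, db = at_nucleus[a], at_nucleus[b]
                if (
                    min(da.sigma, db.sigma) > th.negligible_ratio * sigma_max
                    and abs(_cos(da.d, db.d)) >= th.cos_thresh
                ):
                    sharing.update((a, b))
        if sharing:
            return LocoVerdict(
                nucleus=nucleus,
                excited_modes=tuple(excited),
                verdict="combination",
                competing_modes=tuple(sorted(sharing)),
                rationale="rule_c",
            )

    # otherwise: the excitation is visible iff at least one excited mode
    # survives the single-mode comparison
    any_visible = False
    competitors_seen: set = set()
    for k in excited:
        dk = at_nucleus[k]
        if dk.sigma <= th.negligible_ratio * sigma_max:
            continue  # this mode barely moves the nucleus
        comp = [
            md
            for m, md in at_nucleus.items()
            if m != k and abs(_cos(dk.d, md.d)) >= th.cos_thresh and md.sigma > 0
        ]
        proj_var = sum((md.sigma * _cos(dk.d, md.d)) ** 2 for md in comp)
        if proj_var < th.mask_variance_ratio * dk.sigma**2:
            any_visible = True
        competitors_seen.update(md.mode for md in comp)

    return LocoVerdict(
        nucleus=nucleus,
        excited_modes=tuple(excited),
        verdict="visible" if any_visible else "masked",
        competing_modes=tuple(sorted(competitors_seen)),
        rationale="rule_a" if any_visible else "rule_b",
    )


@dataclass(frozen=True)
class LocoReport:
    """Verdict table for a list of states; one row per (state, nucleus)."""

    rows: tuple = field(default=())

    def to_dict(self) -> dict:
        return {"verdicts": [dict(r) for r in self.rows]}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_text(self) -> str:
        if not self.rows:
            return "(no excited states)\n"
        lines = [f"{'state':<14}{'nucleus':<10}{'verdict':<14}{'rule':<8}competing modes"]
        for r in self.rows:
            lines.append(
                f"{r['state']:<14}{r['nucleus_label']:<10}{r['verdict']:<14}"
                f"{r['rationale']:<8}{r['competing_modes']}"
            )
        return "\n".join(lines) + "\n"


def loco_report(
    modes: NormalModeSet,
    system: MolecularSystem,
    states,
    thresholds: LocoThresholds | None = None,
) -> LocoReport:
    """Verdicts for every (state, nucleus) pair; ground states yield no rows."""
    disp = mode_displacements(modes, system)
    rows = []
    for state in states:
        if not isinstance(state, VibrationalState):
            state = VibrationalState(state)
        state.validate_against(modes)
        excited = [k for k, n in enumerate(state.n) if n > 0]
        if not excited:
            continue
        vib_idx = list(modes.vibrational_indices)
        label = "(" + ",".join(str(state.n[k]) for k in vib_idx) + ")"
        for j in range(system.n_nuclei):
            v = loco_predict(disp, excited, j, thresholds)
            rows.append(
                {
                    "state": label,
                    "nucleus": j,
                    "nucleus_label": f"{j}:{system.labels[j]}",
                    "verdict": v.verdict,
                    "rationale": v.rationale,
                    "competing_modes": list(v.competing_modes),
                    "excited_modes": list(v.excited_modes),
                }
            )
    return LocoReport(rows=tuple(rows))
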