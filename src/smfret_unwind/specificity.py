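"""Unwinding promiscuity and specificity S across Cas9/gRNA conditions.

Promiscuity penalizes unwinding of mismatched targets in proportion to the
number of PAM-distal mismatches::

    promiscuity = sum_{n_PD = 1..3} n_PD * f_unwound(n_PD)

and specificity is the ratio of on-target activity to promiscuity::

    S = f_unwound(0) / promiscuity

An ideal enzyme has high on-target unwinding and low promiscuity, hence a
high S.  Truncated gRNAs (X18, gX18, X17) cannot pair the full 20-nt
protospacer, so promiscuity and S are not defined for them; their on-target
activity is still reported.  f_unwound(4), when measured, never enters S.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .containers import MismatchProfile, SpecificityResult

__all__ = ["compute_promiscuity", "compute_S", "compare_conditions", "plot_specificity_plane"]

PROMISCUITY_N_PDS = (1, 2, 3)


def compute_promiscuity(profile: MismatchProfile) -> tuple[float, float]:
    """Mismatch-weighted aggregate unwinding, with quadrature SD.

    Returns (promiscuity, sd); conditions at different n_PD are independent
    experiments, so variances add as sum (n_PD * sd_n)^2.
    """
    profile.require(PROMISCUITY_N_PDS)
    value = 0.0
    var = 0.0
    for n_pd in PROMISCUITY_N_PDS:
        est = profile.estimates[n_pd]
        value += n_pd * est.f_unwound
        var += (n_pd * est.sd) ** 2
    return value, math.sqrt(var)


def compute_S(profile: MismatchProfile) -> SpecificityResult:
    """Specificity S = on-target f_unwound over promiscuity.

    Uncertainty is first-order (delta-method) propagation of the ratio::

        sd_S = sqrt((sd_0 / P)^2 + (f_0 * sd_P / P^2)^2)

    Raises when promiscuity is exactly zero (a perfectly specific enzyme:
    report on-target and promiscuity without S) and returns S = None for
    truncated-gRNA profiles, for which S is undefined.
    """
    profile.require((0,))
    on_target = profile.estimates[0]
    if profile.is_truncated:
        return SpecificityResult(
            label=profile.label,
            grna=profile.grna,
            on_target=on_target.f_unwound,
            on_target_sd=on_target.sd,
            promiscuity=float("nan"),
            promiscuity_sd=float("nan"),
            s=None,
            sd_s=None,
        )
    prom, prom_sd = compute_promiscuity(profile)
    if prom == 0.0:
        raise ZeroDivisionError(
            f"S undefined: zero promiscuity for {profile.label!r} "
            "(report on_target and promiscuity without S)"
        )
    s = on_target.f_unwound / prom
    sd_s = math.sqrt((on_target.sd / prom) ** 2 + (on_target.f_unwound * prom_sd / prom**2) ** 2)
    return SpecificityResult(
        label=profile.label,
        grna=profile.grna,
        on_target=on_target.f_unwound,
        on_target_sd=on_target.sd,
        promiscuity=prom,
        promiscuity_sd=prom_sd,
        s=s,
        sd_s=sd_s,
    )


def compare_conditions(profiles: Sequence[MismatchProfile]) -> pd.DataFrame:
    """Cross-condition comparison table, sorted by S descending.

    One row per condition: label, grna, on_target, promiscuity, S, sd_S.
    Truncated-gRNA rows carry empty S/promiscuity but keep on_target, as do
    canonical profiles that lack the full n_PD 0-3 set (S not computable
    from partial data).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate condition labels: {dupes}")
    rows = []
    for p in profiles:
        try:
            res = compute_S(p)
        except KeyError:
            on = p.estimates.get(0)
            rows.append(
                {
                    "label": p.label,
                    "grna": p.grna,
                    "on_target": on.f_unwound if on else float("nan"),
                    "on_target_sd": on.sd if on else float("nan"),
                    "promiscuity": float("nan"),
                    "promiscuity_sd": float("nan"),
                    "S": float("nan"),
                    "sd_S": float("nan"),
                }
            )
            continue
        rows.append(
            {
                "label": res.label,
                "grna": res.grna,
                "on_target": res.on_target,
                "on_target_sd": res.on_target_sd,
                "promiscuity": res.promiscuity,
                "promiscuity_sd": res.promiscuity_sd,
                "S": float("nan") if res.s is None else res.s,
                "sd_S": float("nan") if res.sd_s is None else res.sd_s,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("S", ascending=False, na_position="last").reset_index(drop=True)


def plot_specificity_plane(table: pd.DataFrame, path) -> None:
    """On-target activity vs promiscuity scatter, one point per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sub = table.dropna(subset=["promiscuity"])
    ax.errorbar(
        sub["promiscuity"],
        sub["on_target"],
        xerr=sub["promiscuity_sd"],
        yerr=sub["on_target_sd"],
        fmt="o",
        capsize=3,
    )
    for rec in sub.itertuples(index=False):
        ax.annotate(rec.label, (rec.promiscuity, rec.on_target), fontsize=8,
                    xytext=(4, 4), textcoords="offset points")
    ax.set_xlabel("unwinding promiscuity")
    ax.set_ylabel("on-target unwinding activity")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
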