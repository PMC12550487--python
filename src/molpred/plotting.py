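"""Figure helpers for fitted results (matplotlib)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["plot_digestion_curves", "plot_daily_rates", "plot_ppc"]


def _pooled(results, name):
    reg = results.registry
    return results.posterior[name].reshape(-1, reg.n_prey, reg.n_predators)


def plot_digestion_curves(results, predators: Optional[Sequence[str]] = None,
                          n_curves: int = 40, t_max: float = 72.0, ax=None):
    """Posterior digestion curves per pair: bold posterior-mean curve
    plus a spaghetti of random posterior draws."""
    import matplotlib.pyplot as plt
    from scipy.special import expit

    reg = results.registry
    predators = list(predators or reg.predators[:4])
    b0 = _pooled(results, "beta0")
    b1 = _pooled(results, "beta1")
    t = np.linspace(0.0, t_max, 200)
    fig, axes = plt.subplots(len(reg.prey), len(predators),
                             figsize=(3 * len(predators), 2.2 * len(reg.prey)),
                             squeeze=False, sharex=True, sharey=True)
    rng = np.random.default_rng(0)
    take = rng.choice(b0.shape[0], size=min(n_curves, b0.shape[0]), replace=False)
    for ip, prey in enumerate(reg.prey):
        for j, pred in enumerate(predators):
            ic = reg.predator_index(pred)
            ax = axes[ip][j]
            for s in take:
                ax.plot(t, expit(b0[s, ip, ic] - b1[s, ip, ic] * t),
                        color="0.8", lw=0.5)
            ax.plot(t, expit(b0[:, ip, ic].mean() - b1[:, ip, ic].mean() * t),
                    color="crimson", lw=2)
            if ip == 0:
                ax.set_title(pred)
            if j == 0:
                ax.set_ylabel(f"{prey}\nP(detect)")
    axes[-1][0].set_xlabel("hours since feeding")
    fig.tight_layout()
    return fig


def plot_daily_rates(results, ax=None):
    """Boxplots of posterior daily predation rates, one panel per prey."""
    import matplotlib.pyplot as plt

    reg = results.registry
    daily = _pooled(results, "daily_rate")
    fig, axes = plt.subplots(reg.n_prey, 1,
                             figsize=(max(6, 0.4 * reg.n_predators),
                                      2.2 * reg.n_prey),
                             squeeze=False, sharex=True)
    for ip, prey in enumerate(reg.prey):
        ax = axes[ip][0]
        ax.boxplot([daily[:, ip, ic] for ic in range(reg.n_predators)],
                   showfliers=False)
        ax.set_ylabel(f"{prey}\nevents/day")
    axes[-1][0].set_xticks(range(1, reg.n_predators + 1),
                           reg.predators, rotation=90, fontsize=7)
    fig.tight_layout()
    return fig


def plot_ppc(results, field=None, prey: Optional[str] = None, ax=None):
    """Posterior detection-probability boxes against observed frequencies."""
    import matplotlib.pyplot as plt

    ppc = results.posterior_predictive_check(field)
    if prey is not None:
        ppc = ppc[ppc["prey"] == prey]
    ppc = ppc.sort_values("n", ascending=False).reset_index(drop=True)
    reg = results.registry
    p = _pooled(results, "p_detect")
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(ppc)), 4)) \
        if ax is None else (ax.figure, ax)
    data = [p[:, reg.prey_index(r.prey), reg.predator_index(r.predator_code)]
            for r in ppc.itertuples()]
    ax.boxplot(data, showfliers=False)
    ax.plot(range(1, len(ppc) + 1), ppc["observed_freq"], "r*", ms=9,
            label="observed frequency")
    ax.set_xticks(range(1, len(ppc) + 1),
                  [f"{r.predator_code}/{r.prey}" for r in ppc.itertuples()],
                  rotation=90, fontsize=7)
    ax.set_ylabel("P(positive test)")
    ax.legend()
    fig.tight_layout()
    return fig
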