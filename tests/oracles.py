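"""Independent numeric oracles used by the test-suite only."""

import numpy as np
from scipy import integrate, optimize, stats


def oracle_posterior(a, e, prior):
    """Posterior EBGM / EB05 / EB025 by brute-force numeric integration.

    Works from the unnormalized density Poisson(a | lam*E) x mixture-gamma
    prior directly, independent of the conjugate negative-binomial algebra
    used by the implementation.
    """
    def unnorm(lam):
        pois = stats.poisson.pmf(a, lam * e)
        pri = (prior.p_mix * stats.gamma.pdf(lam, prior.alpha1,
                                             scale=1 / prior.beta1)
               + (1 - prior.p_mix) * stats.gamma.pdf(lam, prior.alpha2,
                                                     scale=1 / prior.beta2))
        return pois * pri

    hi = (a + 50) / e + 50
    mode = max((a + 1) / e, 0.1)  # breakpoint near the posterior bulk
    kw = dict(limit=500, epsabs=1e-13, epsrel=1e-11)
    z, _ = integrate.quad(unnorm, 0, hi, points=[mode], **kw)
    mean_ln, _ = integrate.quad(lambda l: np.log(l) * unnorm(l) / z, 1e-12,
                                hi, points=[mode], **kw)

    def cdf(lam):
        v, _ = integrate.quad(unnorm, 0, lam,
                              points=[mode] if lam > mode else None, **kw)
        return v / z

    q05 = optimize.brentq(lambda l: cdf(l) - 0.05, 1e-9, hi, xtol=1e-12)
    q025 = optimize.brentq(lambda l: cdf(l) - 0.025, 1e-9, hi, xtol=1e-12)
    return np.exp(mean_ln), q05, q025
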