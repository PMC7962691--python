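"""Independent oracles used by the test suite.

The exact Riemann solver below is the classical closed-form solution of
the 1D Euler Riemann problem (pressure iteration on the two-wave
function), kept deliberately independent of the package's HLLC flux so it
can serve as ground truth for shock-tube validation.
"""

import numpy as np
from scipy.optimize import brentq


def exact_riemann(rhoL, uL, pL, rhoR, uR, pR, gamma, x_over_t):
    """Exact solution of the 1D Euler Riemann problem sampled at x/t.

    Returns an array (3, len(x_over_t)) of (rho, u, p).
    """
    aL = np.sqrt(gamma * pL / rhoL)
    aR = np.sqrt(gamma * pR / rhoR)
    g1 = (gamma - 1) / (2 * gamma)
    g2 = (gamma + 1) / (2 * gamma)

    def f_side(p, pK, rhoK, aK):
        if p > pK:  # shock branch
            A = 2 / ((gamma + 1) * rhoK)
            B = (gamma - 1) / (gamma + 1) * pK
            return (p - pK) * np.sqrt(A / (p + B))
        return 2 * aK / (gamma - 1) * ((p / pK) ** g1 - 1)

    func = lambda p: (f_side(p, pL, rhoL, aL) + f_side(p, pR, rhoR, aR)
                      + uR - uL)
    pstar = brentq(func, 1e-10, 100 * max(pL, pR), xtol=1e-14, rtol=1e-14)
    ustar = 0.5 * (uL + uR) + 0.5 * (f_side(pstar, pR, rhoR, aR)
                                     - f_side(pstar, pL, rhoL, aL))

    out = np.zeros((3, np.size(x_over_t)))
    for i, s in enumerate(np.atleast_1d(x_over_t)):
        if s <= ustar:  # left of the contact
            if pstar > pL:  # left shock
                sh = uL - aL * np.sqrt(g2 * pstar / pL + g1)
                if s < sh:
                    rho, u, p = rhoL, uL, pL
                else:
                    rho = rhoL * ((pstar / pL + (gamma - 1) / (gamma + 1))
                                  / ((gamma - 1) / (gamma + 1)
                                     * pstar / pL + 1))
                    u, p = ustar, pstar
            else:  # left rarefaction
                astar = aL * (pstar / pL) ** g1
                if s < uL - aL:
                    rho, u, p = rhoL, uL, pL
                elif s > ustar - astar:
                    rho = rhoL * (pstar / pL) ** (1 / gamma)
                    u, p = ustar, pstar
                else:
                    u = 2 / (gamma + 1) * (aL + (gamma - 1) / 2 * uL + s)
                    a = aL - (gamma - 1) / 2 * (u - uL)
                    rho = rhoL * (a / aL) ** (2 / (gamma - 1))
                    p = pL * (a / aL) ** (2 * gamma / (gamma - 1))
        else:
            if pstar > pR:  # right shock
                sh = uR + aR * np.sqrt(g2 * pstar / pR + g1)
                if s > sh:
                    rho, u, p = rhoR, uR, pR
                else:
                    rho = rhoR * ((pstar / pR + (gamma - 1) / (gamma + 1))
                                  / ((gamma - 1) / (gamma + 1)
                                     * pstar / pR + 1))
                    u, p = ustar, pstar
            else:  # right rarefaction
                astar = aR * (pstar / pR) ** g1
                if s > uR + aR:
                    rho, u, p = rhoR, uR, pR
                elif s < ustar + astar:
                    rho = rhoR * (pstar / pR) ** (1 / gamma)
                    u, p = ustar, pstar
                else:
                    u = 2 / (gamma + 1) * (-aR + (gamma - 1) / 2 * uR + s)
                    a = aR + (gamma - 1) / 2 * (u - uR)
                    rho = rhoR * (a / aR) ** (2 / (gamma - 1))
                    p = pR * (a / aR) ** (2 * gamma / (gamma - 1))
        out[:, i] = (rho, u, p)
    return out
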