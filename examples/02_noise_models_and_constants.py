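"""The noise densities behind relative-error losses and their constants.

The product loss (LPRE) and squared-sum loss (LSRE) induce proper
densities h(eps) ~ eps^-1 exp(-rho(eps)) for the multiplicative noise.
This script prints their normalizing constants, the integrals C(gamma, h)
entering the gamma-likelihood, and the influence kernel u_h."""

import numpy as np

import relgamma as rg

k0 = rg.bessel_k_quad(0.0, 2.0)
print(f"K0(2) by quadrature of the integral representation: {k0:.6f}")
print(f"  -> LPRE normalizing constant 1/(2 K0(2)) = {1 / (2 * k0):.6f}")
print(f"LSRE normalizing constant C_LSRE = {rg.lsre_normconst():.6f}")

lpre = rg.make_noise_model("lpre")
lsre = rg.make_noise_model("lsre")
print("\nintegral of h (must be 1):",
      f"lpre={lpre.integral_h_power(1.0):.10f}",
      f"lsre={lsre.integral_h_power(1.0):.10f}")

print("\nC(gamma, h) = int h^(1+gamma)  (Bessel closed form for LPRE):")
for g in (0.1, 0.5, 1.0):
    c_lpre = rg.c_gamma_h(lpre, g)
    c_lsre = rg.c_gamma_h(lsre, g)
    print(f"  gamma={g:4.1f}:  lpre {c_lpre:.6f}   lsre {c_lsre:.6f}")

print("\ninfluence kernel u_h(z) = 1 + z h'(z)/h(z)  (lpre: 1/z - z):")
for z in (0.5, 1.0, 2.0):
    print(f"  z={z}: lpre {lpre.u_h(z):+.4f}   lsre {lsre.u_h(z):+.4f}")
print("u_h(1) = 0: an observation fitted exactly exerts no pull.")
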