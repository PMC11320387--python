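"""The two regimes of release kinetics, without solving any PDE.

The mean escape time splits into an interior-diffusion term b^2/(15 D*)
and a barrier term (b^2/(3 D_w)) e^{-beta dG}.  Whichever dominates defines
the regime: diffusion-limited (large/slow molecules) or reaction-limited
(small molecules strongly attracted to the gel).
"""

from gelrelease import analytic

b, D_w = 100.0, 1.0  # nm, nm^2/ns (times below are in tau0 = 1 ns units)

print(f"{'D*/D_w':>8} {'beta_dG':>8} {'interior':>12} {'barrier':>12} "
      f"{'tau_1/2':>12}  regime")
for ratio in (1e-3, 1e-1):
    for beta_dG in (0.0, -5.0):
        res = analytic.escape_time(b, ratio * D_w, D_w, beta_dG)
        tau_half = analytic.analytic_half_release_time(b, ratio * D_w, D_w, beta_dG)
        regime = ("diffusion-limited" if res.term_interior > res.term_barrier
                  else "reaction-limited")
        print(f"{ratio:8.0e} {beta_dG:8.1f} {res.term_interior:12.0f} "
              f"{res.term_barrier:12.0f} {tau_half:12.0f}  {regime}")

# slow molecules (D*/D_w = 1e-3) release on the same timescale whatever the
# attraction; fast molecules (1e-1) are held back only by the free-energy
# well, with the Arrhenius factor e^{|beta_dG|} setting the timescale
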