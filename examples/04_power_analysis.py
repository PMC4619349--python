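"""Analytic power analysis: break-even tagging and required sample sizes.

The non-centrality of the 1-df interaction Wald test is
N * v * rho2_tag.  Because the three study designs pay very different
Bonferroni corrections (all pairs among 20M sequence variants, 1M GWAS
SNPs, or 1,000 ancestry segments), a design with worse tagging can still
win on its smaller multiple-testing burden.
"""

from admixepi import bonferroni_alpha, breakeven_rho, required_sample_size

alpha_s = bonferroni_alpha(0.05, 2 * 10**7)
alpha_g = bonferroni_alpha(0.05, 10**6)
alpha_l = bonferroni_alpha(0.05, 1000)
print(f"corrected alphas: sequence {alpha_s:.2e}, GWAS {alpha_g:.2e}, "
      f"ancestry {alpha_l:.2e}")

print(f"rho_GC to match the sequence design: "
      f"{breakeven_rho(alpha_g, alpha_s, 0.8):.3f} (~0.9)")
print(f"rho_LC to match the sequence design: "
      f"{breakeven_rho(alpha_l, alpha_s, 0.8):.3f} (~0.7)")

v = 0.01
print(f"\nsample size for 80% power at interaction variance v = {v:.0%}:")
for name, alpha, rho2 in [("sequence, perfect tagging", alpha_s, 1.0),
                          ("GWAS, rho_GC = 0.9", alpha_g, 0.81),
                          ("ancestry, rho_LC = 0.7", alpha_l, 0.49),
                          ("ancestry, rho_LC = 0.8", alpha_l, 0.64)]:
    n = required_sample_size(v, rho2, alpha, 0.8)
    print(f"  {name:<28}: N = {n:>8.0f}")
print("above rho_LC ~ 0.8 the ancestry design needs fewer samples than a "
      "perfectly tagged GWAS design.")
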