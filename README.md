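# hetmap

Systems mapping of quantitative trait loci (QTLs) that govern the
transition dynamics between two interconverting cell subpopulations —
the kind of population heterogeneity seen when a clonal progenitor
population splits into, say, Sca-1 high and Sca-1 low fractions that
regenerate each other over weeks of culture.

`hetmap` is for statistical geneticists and quantitative cell biologists
who have (i) longitudinal measurements of two subpopulation sizes per
individual and (ii) a SNP genotype per individual, and who want to ask:
*is there a locus whose alleles change the kinetic parameters of the
transition process?*

## The model

Each individual's expected trajectory is the solution of a growth and
state-transition ODE system. Linear model:

    dx1/dt = r x1 − k1 x1 + k2 x2
    dx2/dt = r x2 + k1 x1 − k2 x2

with common growth rate *r* and transition rates *k1* (x1→x2) and *k2*
(x2→x1); a nonlinear variant adds state-dependent feedback
−k3 w2 x1 + k4 w1 x2 with w_i the subpopulation proportions. Both models
conserve total growth: x1 + x2 = (x1(0)+x2(0)) e^{rt}.

The QTL has three alleles — Q, q, and a methylated epiallele q⁺ — giving
six genotypes (QQ, Qq, Qq⁺, qq, qq⁺, q⁺q⁺), each with its own ODE
parameter set Θ. The QTL is not observed directly; it is linked to a
biallelic SNP marker (M/m) through linkage disequilibria D₁, D₂, so each
individual's 2T-dimensional phenotype vector
Y = (x1(1..T), x2(1..T)) follows a six-component multivariate-normal
mixture with marker-dependent weights π(j | m). Residuals follow a
bivariate first-order structured antedependence process, SAD(1): each
time's residual pair depends linearly on the previous pair plus a
correlated innovation, giving a structured 2T×2T covariance with a
closed-form log-determinant T·log(ν₁²ν₂²(1−ρ²)).

Estimation is a generalized EM: an E-step over QTL genotypes, a
closed-form haplotype-frequency M-step (expected haplotype counting with
phase weights), and blockwise Nelder–Mead updates of the genotype ODE
parameters (evaluated by fourth-order Runge–Kutta) and the SAD(1)
parameters. QTL existence is tested with a likelihood ratio against a
single-curve null, calibrated by permuting marker labels against intact
phenotype vectors.

## Worked example

```python
import hetmap as hm

# one of the bundled study designs: linear model, n=200,
# nominal heritability label 0.05
sc = hm.build_scenario("linear_n200_h005")
data = hm.simulate_dataset(sc, seed=2)

fit = hm.fit_full(data, "linear", hm.FitConfig(n_starts=2, seed=3))
print(round(fit.loglik, 1))
print(fit.theta[5].round(4))     # fitted (r, k1, k2) for genotype QQ
print(round(fit.genetics.p_M, 3), round(fit.genetics.q_Q, 3))
```

prints

```
11421.9
[0.1199 0.     0.0029]
0.59 0.432
```

— the QQ growth rate is recovered essentially exactly (generating value
r=0.12), and the back-solved marker allele frequency 0.59 and QTL allele
frequency 0.432 sit near the generating 0.6 and 0.4. The individual
transition rates land on a near-equivalent solution ((0, 0.0029) instead
of the generating (0.003, 0.006)): over a nine-point window the slow QQ
transition kinetics constrain mainly the *net* flux, so k1 and k2 are
only weakly identified separately — the fitted curve is visually
indistinguishable from the generating one. The same pipeline is available
from the shell:

```
hetmap simulate --scenario linear_n200_h005 --seed 1 \
    --out-pheno pheno.csv --out-markers markers.tsv
hetmap fit --pheno pheno.csv --markers markers.tsv --model linear \
    --seed 3 --out fit.json
hetmap test --pheno pheno.csv --markers markers.tsv --n-perm 100 \
    --out lr.json
```

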