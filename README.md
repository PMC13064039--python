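# bindkinetics

Analysis pipeline for fluorescence-titration studies of small-molecule
binding to transport proteins (the serum-albumin drug-binding experiment):
how strongly a ligand binds, with what stoichiometry, by what quenching
mechanism, driven by which intermolecular forces, and at which site.

Given titration tables of quencher concentration versus protein
fluorescence (with optional absorbances for inner-filter correction) and
supporting spectra, the package computes:

- **Inner-filter correction** — F_corr = F_obs·10^((A_ex+A_em)/2)
- **Stern–Volmer quenching** — F₀/F = 1 + K_SV[Q]; K_q = K_SV/τ₀; static vs
  dynamic mechanism from the temperature trend of K_SV and the magnitude of
  K_q against the diffusion limit (2×10¹⁰ L mol⁻¹ s⁻¹)
- **Binding constant and stoichiometry** — log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q]
- **van't Hoff thermodynamics** — ln K_b = −ΔH/RT + ΔS/R; ΔG = ΔH − TΔS;
  Ross-type force classification from the signs of (ΔH, ΔS)
- **Spectral evidence** — synchronous-fluorescence residue shifts
  (Δλ = 60 nm tryptophan / 15 nm tyrosine), FTIR amide I/II band shifts,
  UV-vis titration features and Beer–Lambert molar absorptivity
- **Competition analysis** — Sudlow site assignment from site-marker
  displacement (phenylbutazone/diazepam) and metal-ion modulation labels
- **Synthetic experiments** — a seeded generator that inverts every forward
  model exactly, so each estimator is testable by round-trip recovery

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

Simulate a static-quenching ladder with known constants and run the full
quenching → binding → thermodynamics chain:

```python
import bindkinetics as bk

cfg = bk.SyntheticConfig(
    mode="stern_volmer",
    ksv={303.0: 1.07e4, 310.0: 0.82e4, 318.0: 0.48e4},
    temperatures=(303.0, 310.0, 318.0),
    ife=bk.IFEConfig(),          # A_ex rising 0.08 -> 0.42 over the titration
)
fits = []
for T, series in bk.generate_titration(cfg).series_by_T.items():
    fit = bk.fit_stern_volmer(bk.correct_series(series))
    fits.append(fit)
    print(f"T = {T:g} K  K_SV = {fit.ksv:.3g} L/mol  K_q = {fit.kq:.3g} L/mol/s")
call = bk.classify_mechanism(fits)
print(f"mechanism: {call.mechanism}")

thermo_cfg = bk.SyntheticConfig(mode="double_log", ksv=None,
                                delta_h=133.024, delta_s=0.487, n_sites=1.0)
bfits = [bk.fit_double_log(s)
         for s in bk.generate_titration(thermo_cfg).series_by_T.values()]
res = bk.thermo_pipeline(bfits)
print(f"dH = {res.delta_h:.3f} kJ/mol  dS = {res.delta_s:.3f} kJ/mol/K  "
      f"force: {res.force_class}")
```

prints

```
T = 303 K  K_SV = 1.07e+04 L/mol  K_q = 1.07e+12 L/mol/s
T = 310 K  K_SV = 8.2e+03 L/mol  K_q = 8.2e+11 L/mol/s
T = 318 K  K_SV = 4.8e+03 L/mol  K_q = 4.8e+11 L/mol/s
mechanism: static
dH = 133.024 kJ/mol  dS = 0.487 kJ/mol/K  force: hydrophobic
```

The inner-filter distortion is removed exactly, each K_SV is recovered to
machine precision, K_q sits two orders of magnitude above the diffusion
limit while K_SV falls with temperature (the static-quenching signature),
and the positive (ΔH, ΔS) recovered from the temperature dependence of K_b
classify the association as hydrophobically driven (ΔG < 0 at all three
temperatures: −14.5, −17.9, −21.8 kJ/mol).

## Command line

Every analysis is also exposed as a subcommand of `bindkinetics`:

```sh
bindkinetics simulate --config sim.yaml --out-dir sims/
bindkinetics quench --in sims/series_303K.csv --in sims/series_310K.csv \
    --in sims/series_318K.csv --out quench.json
bindkinetics bind --in sims/series_303K.csv --out bind.json
bindkinetics thermo --in bind.json --out thermo.json
bindkinetics sites --blank blank.csv --probe phenylbutazone:site_I_probe:pbz.csv \
    --probe diazepam:site_II_probe:dzp.csv --out sites.json
bindkinetics report --config study.yaml --out report.json --summary report.md
```

`report` runs every configured block (quenching, binding, thermo, modality,
sites, metals) over a directory of inputs and writes one provenance-stamped
JSON study report plus an optional human-readable summary.

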