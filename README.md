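# radkin

Radical-scavenging kinetics from thermochemical descriptors.

`radkin` turns curated Gibbs-energy descriptors of an antioxidant — its
acid–base states and the reaction channels each state offers to the
hydroperoxyl radical (HOO•) — into apparent and overall rate constants at
physiological conditions. The pipeline follows the standard quantum-chemistry
radical-scavenging protocol:

1. **Speciation** — pKa values (or solvation Gibbs energies) give the mole
   fraction of each protonation state at the medium's pH; states below a
   negligibility threshold are dropped.
2. **Thermochemical screening** — channels are kept, flagged borderline, or
   excluded by their reaction Gibbs energy against a configurable cutoff
   (default 5 kcal/mol).
3. **Kinetics** — hydrogen-atom-transfer (HAT) and radical-adduct-formation
   (RAF) channels get conventional transition-state-theory rates with Eckart
   tunneling corrections (or supplied κ factors); single-electron-transfer
   (SET) channels get Marcus-theory barriers from a reorganization energy.
4. **Diffusion correction** — every activation rate is damped through the
   Collins–Kimball expression against the medium's diffusion-limited
   encounter rate (Stokes–Einstein/Smoluchowski from radii and viscosity, an
   explicit override, or a calibrated aqueous default).
5. **Aggregation** — population-weighted channel rates (k_f = f·k_app) sum to
   the overall rate constant; branching ratios Γ and a comparison against
   reference antioxidants (Trolox, ascorbic acid, …) complete the report.

A synthetic-scenario generator with an independent straight-line ground-truth
path supports end-to-end numerical validation.

## Worked example

The package ships the chlorogenic-acid study fixtures. Reproduce the aqueous
results at pH 7.4:

```bash
radkin kinetics \
  --config "$(python -c 'import radkin; print(radkin.fixture_path("table1_water"))')" \
  --out results.md --format markdown
```

`results.md` then contains, for 5-caffeoylquinic acid (5-CQA):

```markdown
### 5-CQA in water

| Mechanism | Site | State | ΔG≠ | κ/λ ^c^ | k_app | f ^a^ | k_f ^b^ | Γ (%) |
|---|---|---|---|---|---|---|---|---|
| HAT | 12OH | mono-anion | 16.8 | 205.7 | 6.60e+02 | 0.918 | 6.06e+02 | 0 |
| HAT | 13OH | mono-anion | 17.5 | 436.8 | 8.40e+01 | 0.918 | 7.71e+01 | 0 |
| RAF | C8 | mono-anion | 19.6 | 1.4 | 2.50e-02 | 0.918 | 2.30e-02 | 0 |
| HAT | 12OH | dianion | 2.0 | 1.2 | 2.30e+09 | 0.082 | 1.89e+08 | 70 |
| RAF | C8 | dianion | 14.2 | 1.0 | 2.40e+02 | 0.082 | 1.97e+01 | 0 |
| SET |  | dianion | 4.8 | 4.0 | 9.70e+08 | 0.082 | 7.95e+07 | 30 |

k_overall = 2.68e+08 M⁻¹s⁻¹
```

The same Python API:

```python
from radkin import fixture_path
from radkin.config import load_config
from radkin.pipeline import run_pipeline

config = load_config(fixture_path("table1_water"))
for result in run_pipeline(config):
    print(result.compound_id, f"{result.k_overall:.3g}")
# 5-CQA 2.68e+08
# 5-FQA 2.28e+07
```

Set `config.options.rate_source = "computed"` to rebuild every rate constant
from its (ΔG≠, κ) or Marcus descriptors instead of taking the tabulated
apparent rates; the two routes agree within the rounding of the inputs.

Other CLI verbs: `speciate` (mole fractions), `screen` (feasibility
verdicts), `report` (reference-antioxidant ranking), `synth` (seeded
synthetic scenarios), `selftest` (re-checks the shipped fixtures).

## Reproduction

```bash
python -m pytest -o addopts= -q tests/        # full suite, ~20 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the headline quantities from the shipped
fixtures alone — the RAF rate of the 5-CQA dianion in water, the RAF and HAT
rates of neutral 5-CQA in pentyl ethanoate, and the Marcus barrier of the
dianion SET channel — and writes them as JSON.

See `docs/methods.md` for the model equations, parameter defaults, and
numerical choices.
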