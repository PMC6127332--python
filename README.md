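# wusham

An equilibrium model of stem-cell-niche patterning in the plant shoot
apical meristem (SAM), for computational biologists studying the
WUSCHEL–CLAVATA3 feedback and the role of the HAM transcription factors.

In the SAM, the epidermis (L1) organises the tissue: it emits a long-range
cytokinin-like signal that activates *WUS* and a short-range repressor
that silences it near the surface, an incoherent feed-forward-like motif
that places the *WUS* domain at a fixed depth. WUS protein moves between
cells, dimerises with HAM proteins, and the monomer/dimer balance reads
out on the *CLV3* promoter (monomers activate, HAM–WUS dimers block),
while the CLV3 peptide diffuses back and represses *WUS*. Per cell the
model tracks ten species — three RNAs (*W*, *H*, *C*), monomers *w*, *h*,
dimer *d*, peptide *c* and three epidermal morphogens — with Hill or
Shea–Ackers transcription kinetics:

    dC/dt = V_C · k_w·w / (1 + k_w·w + k_d·d) − g_C·C

mass-action dimerisation (f·h·w ⇌ b·d), passive diffusion on the cell
graph and a sink at the stem boundary. The package provides:

* **tissue templates** — the canonical 732-cell half-disk (radius 30),
  1D chains, fasciated (clavata-like) and enlarged domes, and a synthetic
  3D template with cell volumes and contact surfaces;
* **equilibrium solvers** — sparse linear solves for diffusing species,
  damped Newton for the monomer/dimer subsystem, and the progressive
  relaxation that closes the CLV3 feedback loop;
* **a six-stage parameter search** (L-BFGS-B with analytic adjoint
  gradients in log-parameter space) against binary target expression
  domains, with the published acceptance filter `Σ(C − C_t)² < 15`;
* **in-silico mutants** — *clavata*, *ham*, *pCLV3::WUS*, enlarged
  meristems, HAM dose series, no-flux lower boundary;
* **analyses** — monomer/dimer mobility profiles, behaviour
  categorisation (central axis / pocket activator / pocket repressor ±)
  and central-axis expression profiles.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Fit one parameter set on the standard template and inspect it:

```python
import wusham as wm

template = wm.build_2d_template(30)          # 732 cells
targets = wm.make_target_domains(template)   # binary W_t / C_t / H_t
result = wm.run_pipeline(seed=0, template=template, targets=targets)

print(result.final_clv3_error, result.accepted)
print(wm.categorize(result.state, template).label)
```

```
1.9108264690387093 True
pocket_repressor
```

The run is accepted (CLV3 error 1.91 < 15) and its equilibrium shows the
pocket-repressor behaviour: a shell of HAM–WUS dimers surrounds the
stem-cell domain and delimits *CLV3* from above, with the WUS-monomer
maximum inside the *WUS* domain (axis height y = 16 ≤ 17). Silencing HAM
collapses *CLV3* onto the *WUS* domain:

```python
params, t = wm.apply_perturbation(result.params, template, "ham")
state = wm.full_equilibrium(params, t)
axis = t.central_axis
print(int(t.coords[axis, 1][state.C[axis].argmax()]),
      int(t.coords[axis, 1][state.W[axis].argmax()]))
```

```
16 16
```

— the *CLV3* and *WUS* peaks now coincide at the same axis height,
the *ham* mutant phenotype.

The same workflows are scriptable from the shell:

```bash
wusham build-template --radius 30 --out template.tsv
wusham optimize --template template.tsv --seeds 0:4 --out results.tsv
wusham simulate --params p.tsv --perturbation clavata --out clv.tsv
wusham dose-series --params p.tsv --doses 0,0.5,1 --out dose.tsv
```

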