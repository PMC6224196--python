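n_cells: 14
cell_diameter: 10.0
contact_range: 55.0
source_strength: 13.0
demand_half: 1.2
uptake: 1.0
decay_C: 0.3
theta_sty: 6.613281788848693
theta_P: 1.8657107124664345
theta_K: 1.6398119692964348
theta_Y: 0.6899874358528219
hill_sty: 3.0
hill_P: 3.0
hill_K: 1.0
hill_Y: 2.0
w_KP: 0.2
w_PK: 0.05
w_PY: 0.2
n_base: 1.0
alpha_n: 0.2
beta_n: 0.4
gamma_n: 0.15
n_floor: 0.9000332037893622
n_cap: 3.0
B_base: 1.0
alpha_B: 0.16
beta_B: 0.25
gamma_B: 0.1
B_floor: 0.2
B_cap: 3.0
long_base: 0.1
long_P: 0.6
long_K: 0.5
long_Y: 0.15
long_floor: 0.11915035328330319
long_cap: 0.9
short_of_rest: 0.65
relax_rate: 0.2
tol: 1.0e-08
max_steps: 100000
mode: deterministic
seed: 0
clones: []
ectopic_sources: []
source_factor: 1.0
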