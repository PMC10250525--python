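# Example grid configuration for `ordgmm run-grid --config ...`.
# Any GridConfig field may appear; omitted fields use the study defaults
# (full K/p/D_KL/N/c grid, 100 repetitions, shared_spherical family).
K_values: [2, 3]
p_values: [4, 10]
kl_values: [2.0, 3.5, 5.0]
N_values: [10000]
c_values: [continuous, 5, 12]
family: component_spherical
reps: 10
base_seed: 7
K_max: 7
n_init: 2
max_iter: 200
tol: 1.0e-6
output_dir: results/example_grid
jobs: 1
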