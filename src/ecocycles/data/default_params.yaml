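# Default parameters of the seasonal eco-evolutionary IPM.
# Fecundity constants
phi1: 1.5
phi2: 2.8
phi3: 0.00007
phi4: 0.04588
phi5: 1.0
phi6: 0.001
# Non-breeding survival constants
ups1: 0.005
ups2: 0.0026
ups3: 0.7
ups4: 0.7
ups5: 6.0
ups6: 350.0
# Environmental-effect slopes (mg per individual)
lamX: 0.00001
lamY: 0.00025
# Variance components (mg^2); h^2 = VA / (VA + VE) = 0.30
VA: 0.003
VE: 0.007
# Trait domain (mg) and quadrature resolution
zmin: 0.0
zmax: 1.0
n_grid: 201
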