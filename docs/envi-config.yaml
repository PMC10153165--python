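# ENVI training configuration (all fields optional; defaults shown).
# Pass to `envi train --config <file>`.

latent_dim: 512          # latent width; large so spatial context fits alongside expression
hidden_layers: [1024, 1024, 1024]  # encoder and decoder trunk widths
beta: 0.3                # KL (prior) coefficient; raise toward 1.0 for small datasets
steps: 16384             # 2^14 ADAM steps
batch_size: 1024         # split half/half between modalities each step
learning_rate: 1.0e-4
final_quarter_lr: null   # optional lower rate for the last quarter of steps, e.g. 1.0e-5
spatial_family: poisson  # poisson | negative_binomial | zinb | normal
sc_family: negative_binomial
covet_k: 8               # niche size (spatial nearest neighbors)
covet_genes: 64          # top panel HVGs used for the COVET representation
covet_transform: raw     # raw | log1p niche expression
hvg_union: 2048          # scRNA-seq genes kept: top HVGs united with the panel
seed: 0
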