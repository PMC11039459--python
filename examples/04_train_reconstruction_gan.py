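"""Train the two-view reconstruction GAN with anatomy guidance.

Stage 1 pretrains the organ segmenter; stage 2 trains the generator and
patch discriminator with the segmenter frozen, logging every loss component.
Desk-scale settings keep the run in CPU minutes.
"""

from topoct import PhantomSpec, TrainConfig, pretrain_segnet, sample_phantom, train_gan

config = TrainConfig.desk_profile(seed=0, epochs_seg=8, epochs_gan=4)
spec = PhantomSpec(grid_size=config.grid_size,
                   voxel_spacing_mm=config.voxel_spacing_mm(), seed=0)
corpus = [sample_phantom(spec, i) for i in range(8)]

segnet, _ = pretrain_segnet(corpus, config)
generator, discriminator, history = train_gan(corpus, segnet, config)

print(f"lambda weights: gen {config.loss_weights.lambda_gen}, "
      f"r {config.loss_weights.lambda_r}, proj {config.loss_weights.lambda_proj}, "
      f"s {config.loss_weights.lambda_s}, p {config.loss_weights.lambda_p}")
for row in history:
    print(f"epoch {row['epoch']}  L_r {row['r']:.4f}  L_proj {row['proj']:.4f}  "
          f"L_s {row['s']:.4f}  L_p {row['p']:.4f}  L_dis {row['dis']:.4f}  "
          f"total {row['total']:.4f}")
# L_r (voxel MSE) and L_proj (topogram MSE) should fall steadily; the
# adversarial terms oscillate around their LSGAN equilibrium near 0.25.
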