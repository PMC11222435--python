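"""Teacher-to-student knowledge distillation with soft labels.

A trained teacher soft-labels an unlabeled example pool with its predicted
probabilities; a smaller student trains on those probabilities directly
(binary cross-entropy with soft targets) and should agree with the teacher's
thresholded calls on held-out data.
"""

import numpy as np

import squigmeth as sq
from squigmeth import model as M
from squigmeth import training as T
from squigmeth.features import FeatureConfig, extract_examples

config = sq.SimConfig(reference_length=8000, seed=9)
reference, truth = sq.simulate_reference(config)
pore = sq.build_pore_model(k=1, mod_shift=1.0, seed=9, levels="spaced")
fc = FeatureConfig(window=15, mode="reference")


def pool(n, seed0):
    out, seed = [], seed0
    while len(out) < n:
        b = sq.simulate_read(reference, truth, pore, config, seed=seed,
                             length=1000, read_id=f"r{seed}")
        out.extend(extract_examples(b, reference, fc))
        seed += 1
    return out


teacher_cfg = M.ModelConfig(latent=32, heads=4, n_enc=1, n_dec=1, d_ff=64,
                            window=15, block_width=5, codebook_size=16, dropout=0.0)
teacher = M.init_params(teacher_cfg, seed=0)
labeled = T.label_from_truth(pool(3000, 0), truth)
teacher, _ = T.train(teacher, teacher_cfg, labeled,
                     T.TrainConfig(batch_size=64, epochs=14, seed=0, alpha=0.1,
                                   learning_rate=1e-3))
print(f"teacher trained on {len(labeled)} hard-labeled examples")

unlabeled = pool(2500, 10_000)
soft = T.distill(teacher, teacher_cfg, unlabeled)
balanced = T.stratified_sample(soft[:2000], 1000, seed=1)
print(f"soft-labeled {len(soft)} examples; stratified sample is exactly "
      f"{sum(e.label > 0.5 for e in balanced)}/{sum(e.label <= 0.5 for e in balanced)}")

student_cfg = M.ModelConfig(latent=32, heads=4, n_enc=1, n_dec=1, d_ff=64,
                            window=15, block_width=5, codebook_size=16, dropout=0.0)
student = M.init_params(student_cfg, seed=1)
student, _ = T.train(student, student_cfg, soft[:2000],
                     T.TrainConfig(batch_size=64, epochs=16, seed=1, alpha=0.1,
                                   learning_rate=1e-3, soft_labels=True))

held = soft[2000:]
teacher_calls = np.array([e.label for e in held]) > 0.5
student_calls = T.predict_probabilities(student, student_cfg, held) > 0.5
print(f"student agrees with teacher on {np.mean(teacher_calls == student_calls):.1%} "
      f"of {len(held)} held-out examples")
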