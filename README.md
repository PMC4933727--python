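# neglectsim

A desk-scale simulator of **unilateral spatial neglect (USN)** — the
post-stroke syndrome in which patients ignore stimuli contralateral to
the damaged cerebral hemisphere.  The package implements a
two-hemisphere artificial neural network that learns to direct spatial
attention to targets on a table from camera-frame visual input and
antagonist neck-muscle input, and provides the full experimental
programme around it: hemisphere lesioning, a four-condition test
battery probing trunk-midline vs line-of-sight reference frames, and
rehabilitation by supervised retraining.

It is intended for computational neuroscientists and neuropsychology
modellers who want a small, fully inspectable network model in which
right-hemisphere specialization for spatial attention *emerges* from
initialization asymmetries, and in which lesion-side-dependent deficit
severity and recovery speed can be measured end to end.

## Model in brief

Per hemisphere *h* ∈ {L, R}, with input **x**ₕ (16 retinal cells + 1
muscle input):

    aₕ = softmax(W₁ₕ xₕ + b₁ₕ)                  (Attention Bias)
    cₕ = σ(W₂ₕ aₕ [+ W×ₕ′ aₕ′] + b₂ₕ)           (Cognition)
    y  = W₃L cL + W₃R cR + b₃                   (shared linear Activator)

`y` is a 16-vector of per-area "likelihoods"; area *i* is explored iff
`y[i] > 0.5`, otherwise the trial is an **omission** (a neglected
target).  Each hemisphere sees the contralateral camera hemifield at
full gain and its own hemifield attenuated (optic-chiasm-style
gradient).  The *control* configuration is symmetric (8+8 units per
hemisphere, init U[−1,1], no cross links); the *specialized*
configuration gives the right hemisphere 4 extra units per layer and
initializes the left hemisphere in U[−0.1,0.1], with inter-hemispheric
attention→cognition links.  Training is full-batch backpropagation with
momentum on MSE against one-hot trunk-centered area labels.  A lesion
zeroes one hemisphere's attention→cognition weights; rehabilitation
re-applies backpropagation in 100-epoch sessions until the battery is
clean.  See `docs/methods.md` for the full account.

## Worked example

```python
from neglectsim import (
    EncoderConfig, NetworkSpec, TrainingConfig, LesionSpec,
    batch_encode, make_training_set, init_network, train_to_convergence,
    apply_lesion, run_battery,
)

enc = EncoderConfig()
batch = batch_encode(make_training_set(enc), enc)

net = init_network(NetworkSpec.specialized(), seed=1)
net, trace = train_to_convergence(net, batch, TrainingConfig())
print(f"trained in {trace.epochs_run} epochs, "
      f"mean correct-target likelihood {trace.final_mean_likelihood:.4f}")

lesioned, record = apply_lesion(net.copy(), LesionSpec(hemisphere="RH"))
report = run_battery(lesioned, enc)
print(f"success {report.success_rate_pct:.2f} %  "
      f"mean likelihood {report.mean_likelihood:.3f}")
print("omissions per condition:", report.omissions_by_condition())
```

prints (seed 1, package defaults):

```
trained in 13552 epochs, mean correct-target likelihood 0.9989
success 65.62 %  mean likelihood 0.694
omissions per condition: {'A': 3, 'B': 1, 'C': 2, 'D': 5}
```

A healthy specialized network explores all 32 battery trials; after the
right-hemisphere lesion the deficit concentrates in the conditions
whose targets fall in the left *camera* hemifield — condition D
(central targets, head turned right) is hit hardest, condition B (right
targets, head straight) barely at all — the signature of an egocentric,
line-of-sight-dependent neglect.

The same programme is scriptable from the shell:

```bash
neglectsim full --test-case specialized --lesion both --rehab \
    --seeds 1,2,3,4,5 --out results/
```

which writes per-seed and cell-wise-median battery CSVs, JSON summaries
and recovery curves (session, omissions, weight-strength-%) under
`results/`.

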