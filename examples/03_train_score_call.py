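"""Train the class-weighted SVM and emit three-way driver calls.

Trains on an imbalanced set (1 driver : 4 passengers), scores the
training mutations, and prints example calls.  A mutation is a driver
if its score beats the 90th percentile of training passenger scores, a
passenger if below the 10th percentile of training driver scores, else
a no-call; the confidence is the fraction of same-class training
mutations with more extreme scores (an empirical tail P value).
"""

from drivercall import FixtureSpec, make_feature_table, predict, train

table, labels = make_feature_table(
    FixtureSpec(
        n_drivers=100, n_passengers=400, n_features=5, n_informative=3,
        effect_size=1.5, seed=3,
    )
)
model = train(table, labels, table.feature_names)
print(f"call thresholds: driver if score > {model.q90_passenger:.3f}, "
      f"passenger if score < {model.q10_driver:.3f}")

calls = predict(model, table)
counts = {c: sum(1 for x in calls if x.category == c)
          for c in ("driver", "no-call", "passenger")}
print(f"calls on the training set: {counts}")
for call in calls[:3]:
    conf = "null" if call.confidence is None else f"{call.confidence:.3f}"
    print(f"  {call.mutation_id}: score={call.score:+.3f} "
          f"category={call.category} confidence={conf}")
# By construction of the percentile rule, at most ~10% of training
# passengers can be called drivers and vice versa.
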