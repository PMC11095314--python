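# Default cross-taxon burst cleaning rules for the sauropsid forelimb comparison.
# Muscle codes: LD latissimus dorsi, PEC pectoralis, SC supracoracoideus,
# TRI_SCAP / TRI_HUM triceps scapular / humeral heads, BB biceps brachii.
- {taxon: Trachemys, muscle: TRI_SCAP, action: group}
- {taxon: Alligator, muscle: SC, action: drop_secondary}
- {taxon: Varanus, muscle: SC, action: drop_secondary}
- {taxon: Sturnus, muscle: BB, action: drop_secondary}
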