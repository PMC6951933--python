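name,cost,min_inclusion,max_inclusion,available,nutrient_0,nutrient_1,nutrient_2
complete_feed,0.40479120971119265,0.0,,,0.7755513759008209,0.943439167964553,0.8789472116237456
feed_1,0.2858192915830861,0.0,6.281136326755458,,0.06592414352135467,0.6829356461457291,0.532797791393247
feed_2,0.24315953602419937,0.0,13.227616132708299,,0.315270156526897,0.25955861696280685,0.6487354921940213
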