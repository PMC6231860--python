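emoji,valence
😊,2.0
😍,2.9
😂,1.6
👍,1.8
🙏,1.4
😁,2.1
🎉,2.4
💕,2.7
😢,-1.9
😡,-2.5
👎,-1.7
💔,-2.6
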