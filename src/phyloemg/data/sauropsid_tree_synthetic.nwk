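((Trachemys:250,(Alligator:245,Sturnus:245):5):30,Varanus:280);
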