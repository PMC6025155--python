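id,label,background,topic,caption,text,attributes
p1,Atenolol,,,Low Libido,"Wow..........is atenolol the answer? Bookish, I hope you get this resolved.... Sincerely, Oleander.",
p2,Diovan,,,Stopped Diovan—Hurrah!!,"Hello, I take Diovan. I missed why you wanted to get off it? Bad side effects?",
p3,Tazorac,,,Should I Give Retin-A Micro the Boot,Tazorac is basically the same thing as Retin A accept it’s supposed to be more potent.,
p4,Trazodone,,,Generic Amb ien!?,"trazodone—nonaddictive, no grogginess and something that I’d suggest to anyone.",
p5,Wellbutrin,,,I am Going to Quit Smoking Soon....but I have Panic Disorder,Wellbutrin really worked for me. I wish I had tried it years ago.
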