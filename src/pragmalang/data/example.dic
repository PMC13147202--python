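%
1	SimpleAffectiveStates
2	ComplexAffectiveStates
3	AffectiveBehaviors
4	CognitiveStates
5	CognitiveBehaviors
6	CausalExplanations
7	StoryElements
8	Characters
%
happy	1
happi*	1
sad	1
angry	1
afraid	1
disgust	1
surprise	1
joy	1
mad	1
shame	2
pride	2
guilt	2
hug	3
smile	3
cry	3
shudder	3
know	4
hope	4
think	4
escape	5
follow	5
hide	5
because	6
since	6
therefore	6
as a result	6
in order to	6
branch	7
family	7
antlers	7
deer	8
dog	8
boy	8
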