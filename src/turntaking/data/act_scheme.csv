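act,description,expected_next,initiating,responding,response_token,valence
decl-q,Declarative Wh-Question,answer;statement,1,0,0,
open,Conventional-opening,,1,0,0,
open-q,Open-Question,neg;affirm;no;yes;statement;reject,1,0,0,
or,Or-Clause,neg;affirm;no;yes;statement;reject,1,0,0,
repeat-q,Signal-non-understanding,,1,0,0,
sum,Summarize/Reformulate,,1,0,0,
tag-q,Tag-Question,neg;affirm;no;yes;statement;reject,1,0,0,
wh-q,Wh-Question,answer;statement;reject,1,0,0,
yn-q,Yes-No-Question,yes;no;affirm;neg;statement,1,0,0,
yn-decl-q,Declarative Yes-No-Question,yes;affirm;statement,1,0,0,
acknowledge,Response Acknowledgment,,0,1,1,
backchannel,Backchannel,,0,1,1,
backchannel-q,Backchannel as question,,0,1,1,
ans-dispref,Dispreferred answers,,0,1,0,negative
hedge,Hedge,,0,1,0,negative
maybe,Maybe/Accept-part,,0,1,0,negative
neg,Negative non-no answers,,0,1,0,negative
no,No answers,,0,1,0,negative
reject,Reject,,0,1,0,negative
affirm,Affirmative non-yes answers,,0,1,0,positive
agree,Agree/Accept,,0,1,0,positive
answer,Other answers,,0,1,0,positive
yes,Yes answers,accept,0,1,0,positive
apprec,Appreciation,,0,1,0,
abandon,Abandoned or Turn-Exit,,0,0,0,
apology,Apology,agree;downplay,0,0,0,
close,Conventional-closing,close,0,0,0,
commit,"Offers, Options, and Commits",,0,0,0,
completion,Collaborative Completion,,0,0,0,
directive,Action-directive,,0,0,0,
downplay,Downplayer,,0,0,0,
excluded,Excluded - bad segmentation,,0,0,0,
hold,Hold before response,,0,0,0,
opinion,Statement-opinion,agree;opinion;disagree;accept,0,0,0,
other,Other,,0,0,0,
third-pty,3rd-party-talk,,0,0,0,
quote,Quotation,,0,0,0,
repeat,Repeat-phrase,agree,0,0,0,
rhet-q,Rhetorical-Questions,agree,0,0,0,
self-talk,Self-Talk,,0,0,0,
statement,Statement-non-opinion,statement,0,0,0,
thank,Thanking,downplay,0,0,0,
uninterp,Uninterpretable,,0,0,0,
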